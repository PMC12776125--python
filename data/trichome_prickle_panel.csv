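trichome_class,Smooth,Bristles,Prickles,Prickles_and_Bristles
Hairy,42,6,0,0
Short_glandular,17,17,132,17
Short_and_elongated_sparse,0,1,63,21
Short_and_elongated_abundant,0,1,3,12
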