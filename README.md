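# pricklemap

Fine mapping of a recessive locus in an autotetraploid, built around the
mapping of the *S* locus that controls prickle development in tetraploid
blackberry (*Rubus* subgenus *rubus*). Prickleless canes require four
copies of the recessive *s* allele, so the locus must be localized with
methods that respect tetrasomic inheritance and allele dosage. The
package implements the three complementary strategies used for this kind
of problem, plus the population and sequencing simulator needed to test
them end to end:

- **Bulked-segregant analysis (BSA)** — pool the affected and unaffected
  progeny of a self, and keep variants whose pooled allele frequencies
  match recessive expectations (mutant bulk AF ≥ 0.95, control bulk
  AF ≤ 0.85). The count of passing variants per 100 kb window (50 kb
  step) localizes the locus.
- **Identity-by-descent (IBD) homozygosity mapping** — affected
  relatives that inherited the same founder haplotype are homozygous
  across the shared segment. Per-sample heterozygous-site counts per
  window (displayed as −[het/median(het)]), intersected across affected
  samples, give a candidate interval whose borders are refined with
  diagnostic SNPs (homozygous in every affected sample, no more than
  heterozygous in every unaffected one) and a 20 kb confirmation scan.
- **Dominance-coded association** — tetraploid dosages (0–4 alt copies)
  collapse to the "1-dom" carrier coding, and each marker is tested
  against the binary trait with a two-sided exact test, Bonferroni
  adjusted, after dosage filters (min DP 2, max missing 5 %, ≥ 5
  minor-allele carriers).
- **Cross statistics** — χ² goodness of fit of observed segregation
  ratios against tetrasomic selfing expectations (with optional double
  reduction), and Cramér's V for trait-by-trait contingency tables.

The simulator generates selfed families and multi-generation IBD panels
under multisomic inheritance: bivalent pairing, Poisson crossovers,
locus-level double reduction, a recessive causal locus, and per-sample or
pooled read counts with depth and error noise.

## Layout

- `src/pricklemap/` — the library: `variants` (VCF/dosage model, sliding
  windows), `simulate` (tetrasomic simulator), `bsa`, `ibd`, `stats`,
  `pipeline`, and the `pricklemap` CLI (`simulate`, `bsa`, `ibd`,
  `gwas`, `stats segregation`, `stats cramers-v`, `full`).
- `analysis/` — numbered drivers reproducing each stage on simulated
  data; tables land in `results/`, bulky exports in `scratch/`.
- `data/trichome_prickle_panel.csv` — the 332-accession diversity-panel
  contingency table (trichome class × prickle class).

## Worked example

```bash
python analysis/02_bsa_scan.py
```

simulates a selfed family of 32 prickleless : 65 prickled progeny from a
parent triplex for the recessive allele (40 Mb chromosome, 2 Morgans,
20,000 SNPs, causal locus at 33.7 Mb), sequences both bulks to ~300×,
and prints:

```
163 variants passed the recessive filter
enriched interval: chr04:31,200,000-36,750,000 (5.55 Mb, peak 7 passing variants/window)
true causal position 33,700,000 is inside the interval
```

The enriched interval is the cluster of windows rich in variants that
segregate like the recessive allele; at this marker density it spans a
few megabases around the true locus. `analysis/03_ibd_mapping.py` then
shows the IBD strategy narrowing the same kind of signal to ~100 kb, and
`analysis/04_association_scan.py` places the top exact-test marker
within ~0.1 Mb of the causal position. `analysis/05_panel_stats.py`
prints the diversity-panel association (χ² = 259.19, V = 0.51) and the
widths of the two published candidate regions: 1.3 Mb
(Ra04:32,950,000–34,250,000, BSA) and 324 kb
(Ri04:30,482,969–30,807,700, IBD).

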