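# Methods

## Trait and inheritance model

The package targets a fully recessive locus in an autotetraploid with
multisomic inheritance: an individual is affected if and only if it
carries zero functional copies of the gene. In the motivating system —
pricklelessness in tetraploid blackberry — the reference genome carries
the dominant (prickled) allele, so throughout the package the causal
allele is by convention the *alt* allele and the affected class is the
quadriplex-alt (dosage 4) class. A polarity flag on the simulator and an
orientation mode on the scans exist to exercise the opposite convention.

Dosage is the count of alt alleles among the four homologous copies
(0 = nulliplex … 4 = quadriplex). "Heterozygous" means dosage 1–3 and
"homozygous" means 0 or 4 — the only reading under which a diagnostic
site can be "homozygous in affecteds and no more than heterozygous in
unaffecteds".

## Meiosis simulator

Each meiosis pairs the four homologs into two bivalents, uniformly over
the three pairings. Each bivalent receives a Poisson(λ = genetic length
in Morgans) number of crossovers at uniform map positions, applied
between the two paired sequences; the gamete takes one product per
bivalent. Crossover interference is ignored (the Poisson model is the
simplest consistent with a map length). Double reduction is modelled at
rate α by duplicating one bivalent's product, which reproduces the
analytic locus-level gamete distribution

    P(gamete dosage k | parent dosage d)
      = (1−α)·Hypergeom(k; d of 4, draw 2) + α·[copy one allele twice]

exactly; α defaults to 0, under which a triplex self segregates 1
affected : 3 unaffected. The simulator's full determinism (same seed ⇒
byte-identical outputs) is tested.

Founder haplotypes: every simulated SNP is heterozygous in the founder
by default (`founder_het = 1.0`). This emulates the ascertainment of a
real mapping family, where the variant list comes from calling variants
on the family's own sequencing and monomorphic sites are never emitted.
Alleles at a heterozygous site are placed at dosage 1–3 with
probabilities proportional to a Binomial(4, ½) truncated to polymorphic,
on random homologs; there is no linkage disequilibrium beyond physical
linkage, which alone generates the block structure the scans exploit.

Read counts: per individual and site, depth ~ Poisson(D) and alt reads ~
Binomial(depth, p) with p = (dosage/4)(1−ε) + (1−dosage/4)ε. Bulks sum
the counts of their members; per-sample mean depth can be set per bulk
so each pool reaches a target coverage (300× per bulk in the study-scale
runs, i.e. ~9.4×/individual in a 32-sample bulk).

The IBD panel generator descends each haplotype of an affected
individual from a single founder haplotype carrying the causal allele,
through m rounds of recombination against a pool of random population
haplotypes (alt frequency 0.5 — a maximally diverse panel, which also
maximizes diagnostic-SNP information), always conditioning on retention
of the founder segment at the causal locus. Unaffected carriers hold 1–3
such descended copies. More meioses ⇒ a shorter shared segment, which is
the signal the interval-width analyses measure.

## BSA scan

Allele frequencies are computed from pooled read counts, never from
genotype calls, because the bulks are pooled before sequencing. Sites
need ≥ 10 reads in each bulk (the depth floor is a package default; at
~300× per bulk it only removes dropout sites). A site passes the
recessive filter iff mutant-bulk causal AF ≥ 0.95 and control-bulk
causal AF ≤ 0.85. The scan statistic is the count of passing variants
per 100 kb window with a 50 kb step; a variant contributes to every
window containing it, so overlapping windows double-count by design.

Enriched-interval calling marks windows with count ≥ max(2, 0.2 × global
max) and merges the cluster of marked windows around the (leftmost)
global maximum, tolerating gaps of up to 8 consecutive unmarked windows;
the interval spans the first to the last marked window of the cluster.
The gap tolerance and the low marking fraction are deliberate: at
realistic marker densities (20,000 SNPs over 40 Mb, of which ~1/14 are
informative for the filter) the enriched plateau holds only ~2–4 passing
variants per window, and Poisson thinning fragments any strictly
contiguous run into noise islands — an estimator requiring contiguity at
half-maximum then returns a sliver that usually misses the locus. With
gap-bridged clustering the called interval covers the plateau (typically
3–6 Mb under those conditions) and contains the causal position in
essentially all replicates. All three knobs (`fraction`, `min_count`,
`max_gap`) are configurable, and `max_gap = 0` restores the strict rule.

No smoothed SNP-index or G′-style statistic is computed; the scan
statistic is deliberately the filtered count.

## IBD mapping

Per affected sample, heterozygous sites are counted per window; the
display metric is m_w = −(het count / median het count over the
chromosome's windows, zeros included), with a documented floor
(normalizer 1) when the median is 0. The metric is scale-invariant and
equals 0 exactly on fully homozygous windows. The median's scope
(per-chromosome) is a package choice; genome-wide normalization would
only rescale all windows of a single-chromosome run identically.

Candidate regions are maximal runs of windows with ≤ h_max heterozygous
calls (default 1, absorbing one genotyping error per window), intersected
across all affected samples. For the synthetic panels the run windows
are 12.5 kb with a 6.25 kb step, chosen so that a shared segment of a
few tens of kb (16 meioses of separation) still spans whole windows at
2,000 SNPs/Mb; the 100 kb display windows of the profile TSVs follow the
field's plotting convention instead. With several samples, the widest
run is taken as the candidate (sharing at the causal locus is enforced
by descent, so incidental pockets of agreement are systematically
shorter), with diagnostic-SNP support as tie-break.

Sites are then classified: *diagnostic* (every affected homozygous for
the same allele, no unaffected homozygous for it), *affected-het* (the
affected samples themselves are not homozygous for one shared allele —
positive evidence against IBD there), or *carrier-homozygous* (only an
unaffected sample is homozygous for the shared allele — non-diagnostic
but carrying no evidence against the interval). Because no affected-het
site can lie strictly inside the true shared region, the run's borders
are first snapped to the nearest affected-het SNP on each side of an
interior anchor (the diagnostic SNP nearest the run midpoint), giving
SNP-resolution borders.

Each snapped border is then confirmed by the 20 kb scan rule: accepted
iff ≥ 3 diagnostic SNPs lie within 20 kb on the interval side, ≥ 3
affected-het SNPs lie within 20 kb on the far side, and at most 1
affected-het SNP lies on the interval side (the veto stops borders
drifting into zones where a single sample's segment has already ended).
A rejected candidate steps outward to the next informative SNP; if
nothing confirms, the border is kept where snapped and flagged
`unconfirmed` rather than moved — a deliberately conservative choice, as
the confirmation scan exists to prevent single discordant calls from
setting false breakpoints, not to relocate borders. Counts of
supporting/contradicting SNPs are reported as boundary provenance.

## Association scan

The "1-dom" coding collapses dosage to carrier/non-carrier of the
dominant allele; ref-dominant is the default (reference = dominant
functional allele), alt-dominant is available. Each marker is tested
with a two-sided exact test on the 2×2 carrier × phenotype table: the
sum of hypergeometric probabilities of all tables no more probable than
the observed one. This is a deliberate, documented simplification — no
kinship or population-structure correction is fitted; for a selfed
mapping family the exact test is correctly calibrated (its permutation
type-I rate is checked) and dependency-light. Degenerate margins yield
NA with a reason string, never an exception. Bonferroni adjustment uses
the number of testable markers; the conventional genome-wide line
p = 5×10⁻⁸ is reported alongside.

The segregation χ² compares observed affected:unaffected counts of a
self against the tetrasomic expectation [P(gamete carries 2 causal
copies)]², with df = 1; expectations of 0 or 1 bypass χ² for an exact
consistency report. Cramér's V uses the plain definition
√(χ²/(N·(min(r,c)−1))) with no continuity correction; zero margins are
dropped with a warning, and a Bergsma bias-corrected variant is exposed
as an option because small-sample V is upward-biased.

## Problem sizes and what the tests show

Study-scale checks run on: a 40 Mb chromosome, 2 Morgans, 20,000 SNPs,
causal locus at 33.7 Mb, a 32:65 selfed family (drawn by per-progeny
rejection to match the observed class sizes), 300× bulks with ε = 0.005,
20 replicates (BSA); 8 affected + 8 carrier panels at 2,000 SNPs/Mb over
8 Mb and 4/8/16 meioses of founder separation, 20 replicates (IBD); and
1,000 phenotype permutations (calibration). These sizes make the full
suite run in about a minute while leaving the per-window counts, depths
and recombination densities at the values stated above.

Passing tests show the pipelines recover a *simulated* recessive locus
under the stated inheritance and noise model. The generator does not
emulate mismapping or paralogy (collapsed repeats producing pseudo-het
sites), variant-calling artifacts, LD beyond physical linkage,
population structure in the IBD panel, phenotyping error, or
cross-assembly coordinate differences — all of which the real analysis
had to contend with (and which motivated, e.g., the 20 kb confirmation
scan). Recovery rates on synthetic data are therefore upper bounds, not
field performance estimates.

## Numerical and degenerate-input choices

- Dosage calling picks the nearest k/4 frequency bin; exact ties break
  toward the lower dosage (deterministic, conservative toward the
  reference allele).
- Missing data: zero-depth frequencies are NaN; sites missing in either
  bulk fail the BSA filter; missing dosages are excluded from het counts
  and disqualify diagnostic sites; missing carrier codes drop out of the
  exact test.
- `min.minor` counts *samples carrying* the minor allele (alt-minor:
  dosage ≥ 1; ref-minor: dosage ≤ 3); allele-copy totals decide which
  allele is minor, ties counting alt as minor.
- Window arithmetic is 0-based half-open internally; VCF positions are
  1-based; BED output is 0-based half-open. Trailing partial windows are
  kept.
- Multiallelic records and indels are skipped (and tallied), not split:
  the scans operate on biallelic SNPs and splitting would change dosage
  semantics.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit configuration; identical seeds give byte-identical outputs.

## Known limitations

- Double reduction is exact at the locus level but approximated at the
  haplotype level (a duplicated bivalent product, not quadrivalent
  pairing with internal recombination).
- The enriched-interval width at desk-scale marker density (a few Mb) is
  much wider than what ~millions of variants would give; only the
  containment property, not the width, is comparable across densities.
- The exact-test scan is not a mixed-model association method and will
  be anticonservative under population structure; it is intended for
  family designs.
- One reference coordinate system per run; no liftover between
  assemblies.
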