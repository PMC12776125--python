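"""Autotetraploid population and sequencing simulator.

Generates selfed families segregating a recessive allele under multisomic
(tetrasomic) inheritance, plus multi-generation identity-by-descent panels,
and turns them into per-sample or pooled-bulk read counts. The recessive
trait model mirrors a prickleless blackberry S locus: the causal allele is
the *alt* allele by default and an individual is affected iff it carries
zero functional (ref) copies, i.e. alt dosage 4.

Meiosis model: the four homologs pair into two bivalents (uniform over the
three pairings); each bivalent receives a Poisson number of crossovers
(mean = genetic length in Morgans), applied at uniform genetic positions
between the two paired sequences; the gamete takes one product per
bivalent. Double reduction (rate ``alpha``) duplicates one bivalent's
product, which reproduces the locus-level gamete pmf exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import GenomeLayout, VariantSite, VcfData, write_phenotypes, write_vcf

__all__ = [
    "SimConfig",
    "ReadModel",
    "SimIndividual",
    "SimPopulation",
    "BulkReadCounts",
    "gamete_dosage_pmf",
    "make_founder",
    "simulate_meiosis",
    "self_cross",
    "ibd_family",
    "simulate_reads",
    "export_population",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated chromosome and cross.

    chrom_length
        physical length in bp.
    genetic_length
        map length in Morgans (crossovers per bivalent per meiosis).
    n_snps
        number of segregating SNP positions (the causal site is forced in).
    causal_pos
        1-based bp position of the recessive causal locus.
    parent_dosage
        founder's alt (causal) dosage at that locus, 0..4; a parent triplex
        for the recessive allele has dosage 3.
    alpha
        double-reduction rate.
    n_progeny
        family size for :func:`self_cross`.
    founder_het
        fraction of SNP sites heterozygous in the founder. The default, 1.0,
        emulates a variant list ascertained by calling variants on the
        family's own sequencing, where every emitted site segregates.
    causal_is_alt
        polarity flag; when False the causal allele is written as ref.
    """

    chrom: str = "chr04"
    chrom_length: int = 40_000_000
    genetic_length: float = 2.0
    n_snps: int = 20_000
    causal_pos: int = 33_700_000
    parent_dosage: int = 3
    alpha: float = 0.0
    n_progeny: int = 97
    founder_het: float = 1.0
    causal_is_alt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 <= self.parent_dosage <= 4:
            raise ValueError("parent_dosage must be in 0..4")
        if not 1 <= self.causal_pos <= self.chrom_length:
            raise ValueError("causal_pos outside chromosome")
        if self.n_progeny <= 0:
            raise ValueError("n_progeny must be positive")
        if self.genetic_length < 0:
            raise ValueError("genetic_length must be non-negative")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout({self.chrom: self.chrom_length})


@dataclass(frozen=True)
class ReadModel:
    """Sequencing noise model: per-individual mean depth and error rate."""

    depth: float = 10.0
    error: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error < 0.5:
            raise ValueError("error must be in [0, 0.5)")


@dataclass
class SimIndividual:
    """Four haplotypes (rows of a (4, n_snps) 0/1 array) plus trait truth."""

    haplotypes: np.ndarray
    causal_dosage: int
    phenotype: int  # 1 = affected (prickleless), 0 = unaffected

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int16)


@dataclass
class SimPopulation:
    """A simulated family with SNP coordinates and causal-locus truth."""

    cfg: SimConfig
    positions: np.ndarray  # 1-based bp, sorted
    causal_index: int
    parent: SimIndividual | None
    individuals: list[SimIndividual]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [f"P{i:04d}" for i in range(1, len(self.individuals) + 1)]

    def dosage_matrix(self) -> np.ndarray:
        """(n_sites, n_samples) alt-dosage matrix."""
        return np.stack([ind.dosages() for ind in self.individuals], axis=1)

    def phenotypes(self) -> dict[str, int]:
        return {n: ind.phenotype for n, ind in zip(self.names, self.individuals)}

    def affected_names(self) -> list[str]:
        return [n for n, i in zip(self.names, self.individuals) if i.phenotype == 1]

    def unaffected_names(self) -> list[str]:
        return [n for n, i in zip(self.names, self.individuals) if i.phenotype == 0]


@dataclass
class BulkReadCounts:
    """Pooled (ref, alt) read counts per site for two phenotype bulks."""

    positions: np.ndarray
    mut_ref: np.ndarray
    mut_alt: np.ndarray
    wt_ref: np.ndarray
    wt_alt: np.ndarray
    chrom: str = "chr04"


def gamete_dosage_pmf(d: int, alpha: float = 0.0) -> dict[int, float]:
    """Distribution of gamete alt dosage {0, 1, 2} from a parent of dosage d.

    Mixture of normal bivalent segregation — a hypergeometric draw of 2 of
    the 4 homologous copies — and double reduction at rate ``alpha``, where
    one copy is drawn uniformly and duplicated.
    """
    if not 0 <= d <= 4:
        raise ValueError("parent dosage must be in 0..4")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    from math import comb

    normal = {k: comb(d, k) * comb(4 - d, 2 - k) / comb(4, 2) for k in range(3)}
    dr = {0: (4 - d) / 4, 1: 0.0, 2: d / 4}
    return {k: (1 - alpha) * normal[k] + alpha * dr[k] for k in range(3)}


def _founder_haplotypes(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Founder's 4 haplotypes, SNP positions, and the causal site index."""
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_snps, replace=False) + 1)
    # force a SNP at the causal position
    ci = int(np.searchsorted(positions, cfg.causal_pos))
    if ci == cfg.n_snps or positions[ci] != cfg.causal_pos:
        ci = min(ci, cfg.n_snps - 1)
        positions[ci] = cfg.causal_pos
        positions = np.sort(positions)
        ci = int(np.searchsorted(positions, cfg.causal_pos))
    haps = np.zeros((4, cfg.n_snps), dtype=np.int8)
    het = rng.random(cfg.n_snps) < cfg.founder_het
    # heterozygous sites get dosage 1..3 ~ Binomial(4, 1/2) truncated to be polymorphic
    dos = rng.choice([1, 2, 3], size=int(het.sum()), p=[4 / 14, 6 / 14, 4 / 14])
    cols = np.flatnonzero(het)
    for j, k in zip(cols, dos):
        haps[rng.permutation(4)[:k], j] = 1
    # causal locus: alt copies on the first parent_dosage haplotypes
    haps[:, ci] = 0
    haps[: cfg.parent_dosage, ci] = 1
    return haps, positions, ci


def make_founder(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimPopulation:
    """Founder individual wrapped in a population shell (no progeny)."""
    rng = rng or np.random.default_rng(cfg.seed)
    haps, positions, ci = _founder_haplotypes(cfg, rng)
    d = int(haps[:, ci].sum())
    parent = SimIndividual(haps, d, int(d == 4))
    return SimPopulation(cfg, positions, ci, parent, [], names=[])


def _recombine_pair(
    h_a: np.ndarray,
    h_b: np.ndarray,
    gpos: np.ndarray,
    genetic_length: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Both complementary crossover products of two paired sequences.

    Crossover count ~ Poisson(genetic length), positions uniform on the map
    (no interference); the two products alternate source sequence at each
    crossover, starting from opposite parents.
    """
    k = rng.poisson(genetic_length)
    first = int(rng.integers(2))
    if k == 0:
        return (h_a.copy(), h_b.copy()) if first == 0 else (h_b.copy(), h_a.copy())
    xo = np.sort(rng.random(k) * genetic_length)
    take = (first + np.searchsorted(xo, gpos)) % 2
    return np.where(take == 0, h_a, h_b), np.where(take == 0, h_b, h_a)


def _recombine(
    h_a: np.ndarray,
    h_b: np.ndarray,
    gpos: np.ndarray,
    genetic_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One crossover product of two paired sequences."""
    return _recombine_pair(h_a, h_b, gpos, genetic_length, rng)[0]


def simulate_meiosis(
    ind: SimIndividual, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """One meiosis: a (2, n_snps) gamete from bivalent pairing + crossovers.

    The four homologs pair uniformly into two bivalents; the gamete takes
    one crossover product from each. With probability ``alpha`` (double
    reduction) one bivalent's product is duplicated instead.
    """
    gpos = _genetic_positions(ind, cfg)
    perm = rng.permutation(4)
    products = [
        _recombine(ind.haplotypes[a], ind.haplotypes[b], gpos, cfg.genetic_length, rng)
        for a, b in ((perm[0], perm[1]), (perm[2], perm[3]))
    ]
    if cfg.alpha > 0 and rng.random() < cfg.alpha:
        which = int(rng.integers(2))
        products = [products[which], products[which].copy()]
    return np.stack(products)


def _genetic_positions(ind: SimIndividual, cfg: SimConfig) -> np.ndarray:
    """Genetic map positions cached on the individual, else uniform spacing."""
    n = ind.haplotypes.shape[1]
    gp = getattr(ind, "_gpos", None)
    if gp is not None and len(gp) == n:
        return gp
    return np.linspace(0.0, cfg.genetic_length, n)


def _attach_gpos(ind: SimIndividual, positions: np.ndarray, cfg: SimConfig) -> None:
    ind._gpos = positions / cfg.chrom_length * cfg.genetic_length  # type: ignore[attr-defined]


def _progeny_from(parent: SimIndividual, cfg: SimConfig, ci: int, rng: np.random.Generator) -> SimIndividual:
    g1 = simulate_meiosis(parent, cfg, rng)
    g2 = simulate_meiosis(parent, cfg, rng)
    haps = np.concatenate([g1, g2])
    d = int(haps[:, ci].sum())
    functional = 4 - d if cfg.causal_is_alt else d
    child = SimIndividual(haps, d, int(functional == 0))
    child._gpos = parent._gpos  # type: ignore[attr-defined]
    return child


def self_cross(
    parent_pop: SimPopulation,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    quota: tuple[int, int] | None = None,
) -> SimPopulation:
    """Self the founder and return a family of progeny.

    With ``quota=(n_affected, n_unaffected)`` progeny are drawn until both
    phenotype classes are filled (rejection sampling), reproducing a family
    with fixed observed segregation counts.
    """
    cfg = parent_pop.cfg
    parent = parent_pop.parent
    if parent is None:
        raise ValueError("population has no founder")
    rng = rng or np.random.default_rng(cfg.seed + 1)
    _attach_gpos(parent, parent_pop.positions, cfg)
    ci = parent_pop.causal_index
    progeny: list[SimIndividual] = []
    if quota is None:
        for _ in range(n if n is not None else cfg.n_progeny):
            progeny.append(_progeny_from(parent, cfg, ci, rng))
    else:
        want = {1: quota[0], 0: quota[1]}
        guard = 0
        while want[0] > 0 or want[1] > 0:
            guard += 1
            if guard > 10_000 * (quota[0] + quota[1] + 1):
                raise RuntimeError("phenotype quota unreachable under this cross")
            child = _progeny_from(parent, cfg, ci, rng)
            if want[child.phenotype] > 0:
                want[child.phenotype] -= 1
                progeny.append(child)
        rng.shuffle(progeny)
    return SimPopulation(cfg, parent_pop.positions, ci, parent, progeny)


def ibd_family(
    cfg: SimConfig,
    n_affected: int = 8,
    n_carriers: int = 8,
    meioses: int = 8,
    pool_size: int = 40,
    pool_alt_freq: float = 0.5,
    rng: np.random.Generator | None = None,
) -> SimPopulation:
    """Distant relatives sharing one founder causal haplotype by descent.

    Each affected individual carries four haplotypes independently descended
    from a single founder haplotype bearing the recessive causal allele,
    each through ``meioses`` rounds of recombination against random
    population haplotypes (always conditioned on retaining the founder
    segment at the causal locus). Unaffected carriers hold 1–3 such
    descended copies. More meioses ⇒ shorter shared segment around the
    locus, which is what interval refinement exploits.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_snps, replace=False) + 1)
    ci = int(np.searchsorted(positions, cfg.causal_pos))
    if ci == cfg.n_snps or positions[ci] != cfg.causal_pos:
        ci = min(ci, cfg.n_snps - 1)
        positions[ci] = cfg.causal_pos
        positions = np.sort(positions)
        ci = int(np.searchsorted(positions, cfg.causal_pos))
    gpos = positions / cfg.chrom_length * cfg.genetic_length

    pool = (rng.random((pool_size, cfg.n_snps)) < pool_alt_freq).astype(np.int8)
    pool[:, ci] = 0  # pool haplotypes carry the functional (ref) allele
    causal_hap = (rng.random(cfg.n_snps) < pool_alt_freq).astype(np.int8)
    causal_hap[ci] = 1

    def descend(m: int) -> np.ndarray:
        # each meiosis yields two complementary products; keep the one whose
        # causal-locus segment comes from the descending (founder) lineage
        h = causal_hap
        for _ in range(m):
            partner = pool[rng.integers(pool_size)]
            prod_a, prod_b = _recombine_pair(h, partner, gpos, cfg.genetic_length, rng)
            h = prod_a if prod_a[ci] == 1 else prod_b
        return h.copy()

    individuals: list[SimIndividual] = []
    names: list[str] = []
    for i in range(n_affected):
        haps = np.stack([descend(meioses) for _ in range(4)])
        individuals.append(SimIndividual(haps, int(haps[:, ci].sum()), 1))
        names.append(f"AFF{i:03d}")
    for i in range(n_carriers):
        k = int(rng.integers(1, 4))
        haps = [descend(meioses) for _ in range(k)]
        haps += [pool[rng.integers(pool_size)].copy() for _ in range(4 - k)]
        haps = np.stack(haps)
        individuals.append(SimIndividual(haps, int(haps[:, ci].sum()), 0))
        names.append(f"CAR{i:03d}")
    return SimPopulation(cfg, positions, ci, None, individuals, names=names)


def simulate_reads(
    pop: SimPopulation,
    model: ReadModel,
    bulks: tuple[Sequence[str], Sequence[str]] | None = None,
    depths: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> BulkReadCounts | tuple[np.ndarray, np.ndarray]:
    """Draw sequencing read counts per individual, optionally pooled.

    Per individual and site, depth ~ Poisson(D) and alt reads ~
    Binomial(depth, p) with p = (dosage/4)(1−ε) + (1−dosage/4)ε. With
    ``bulks`` = (affected sample names, control sample names) the two
    pools' counts are summed and returned as :class:`BulkReadCounts`;
    otherwise per-sample (ref, alt) arrays of shape (n_sites, n_samples)
    are returned. ``depths`` overrides the mean depth per sample (used to
    calibrate pooled bulk coverage).
    """
    rng = rng or np.random.default_rng(model.seed)
    dos = pop.dosage_matrix()  # (sites, samples)
    n_sites, n_samples = dos.shape
    dvec = np.full(n_samples, model.depth)
    if depths:
        for i, name in enumerate(pop.names):
            if name in depths:
                dvec[i] = depths[name]
    depth = rng.poisson(dvec[None, :], size=(n_sites, n_samples))
    p = (dos / 4.0) * (1 - model.error) + (1 - dos / 4.0) * model.error
    alt = rng.binomial(depth, p)
    ref = depth - alt
    if bulks is None:
        return ref, alt
    mut, wt = bulks
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("bulks must be non-empty")
    if set(mut) & set(wt):
        raise ValueError("bulk membership must be disjoint")
    idx = {n: i for i, n in enumerate(pop.names)}
    mi = [idx[n] for n in mut]
    wi = [idx[n] for n in wt]
    return BulkReadCounts(
        positions=pop.positions.copy(),
        mut_ref=ref[:, mi].sum(axis=1),
        mut_alt=alt[:, mi].sum(axis=1),
        wt_ref=ref[:, wi].sum(axis=1),
        wt_alt=alt[:, wi].sum(axis=1),
        chrom=pop.cfg.chrom,
    )


def export_population(
    pop: SimPopulation,
    out_vcf: str | Path,
    out_phen: str | Path,
    out_truth: str | Path,
    reads: tuple[np.ndarray, np.ndarray] | None = None,
    include_parent: bool = True,
) -> VcfData:
    """Write the family as VCF (+AD when reads given), phenotype and truth TSVs."""
    cfg = pop.cfg
    names = list(pop.names)
    inds = list(pop.individuals)
    if include_parent and pop.parent is not None:
        names = ["PARENT"] + names
        inds = [pop.parent] + inds
    dos = np.stack([ind.dosages() for ind in inds], axis=1)
    sites: list[VariantSite] = []
    for j in range(len(pop.positions)):
        depths = None
        if reads is not None:
            ref_r, alt_r = reads
            if include_parent and pop.parent is not None:
                pad = np.zeros((1,), dtype=np.int64)
                depths = np.stack(
                    [np.concatenate([pad, ref_r[j]]), np.concatenate([pad, alt_r[j]])], axis=1
                )
            else:
                depths = np.stack([ref_r[j], alt_r[j]], axis=1)
        ref_allele, alt_allele = ("A", "T") if cfg.causal_is_alt else ("T", "A")
        sites.append(
            VariantSite(cfg.chrom, int(pop.positions[j]), ref_allele, alt_allele, dos[j], depths)
        )
    data = VcfData(sites, names)
    write_vcf(data, out_vcf, layout=cfg.layout)
    write_phenotypes({n: i.phenotype for n, i in zip(names, inds)}, out_phen)
    with open(out_truth, "w") as fh:
        fh.write(f"#causal_chrom={cfg.chrom}\tcausal_pos={cfg.causal_pos}\n")
        fh.write("sample\tcausal_dosage\tphenotype\n")
        for n, i in zip(names, inds):
            fh.write(f"{n}\t{i.causal_dosage}\t{i.phenotype}\n")
    return data
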