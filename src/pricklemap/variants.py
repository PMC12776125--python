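"""Domain types and I/O for tetraploid variant data.

Everything downstream (bulk scans, homozygosity mapping, association)
works on biallelic SNPs with per-sample allele *dosage* — the number of
alternate-allele copies among the four homologous chromosomes of an
autotetraploid (0 = nulliplex … 4 = quadriplex) — plus optional per-sample
allele depths (ref reads, alt reads).

Coordinate conventions: VCF positions are 1-based (as in the format);
window arithmetic is 0-based half-open; BED output is 0-based half-open.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

MISSING = -1  # sentinel for a missing dosage call

__all__ = [
    "MISSING",
    "GenomeLayout",
    "VariantSite",
    "DosageFilterConfig",
    "Window",
    "VcfData",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "allele_frequency",
    "call_dosage",
    "site_filters",
    "make_windows",
    "downsample_sites",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths for one reference coordinate system."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)


@dataclass
class VariantSite:
    """One biallelic SNP with per-sample tetraploid dosages and allele depths.

    ``dosages`` is an int array with :data:`MISSING` (-1) for no-calls.
    ``depths`` is an ``(n_samples, 2)`` array of (ref reads, alt reads),
    or ``None`` when the source carried no AD field.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosages: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        bad = (self.dosages != MISSING) & ((self.dosages < 0) | (self.dosages > 4))
        if bad.any():
            raise ValueError(f"dosage out of range at {self.chrom}:{self.pos}")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int64)
            if (self.depths < 0).any():
                raise ValueError(f"negative allele depth at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class DosageFilterConfig:
    """Site/call filters applied before dosage-based analyses.

    min_dp
        minimum read depth for a per-sample dosage call (below → missing).
    max_missing
        maximum tolerated fraction of missing calls per site.
    min_minor
        minimum number of samples carrying the minor allele.
    """

    min_dp: int = 2
    max_missing: float = 0.05
    min_minor: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if self.min_dp < 0 or self.min_minor < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True, order=True)
class Window:
    """Half-open genomic window [start, end), 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad window [{self.start}, {self.end})")

    def contains(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass
class VcfData:
    """Parsed VCF payload: site list, sample order, and a skip report."""

    sites: list[VariantSite]
    samples: list[str]
    skipped: dict[str, int] = field(default_factory=dict)

    def dosage_matrix(self) -> np.ndarray:
        """(n_sites, n_samples) int matrix of dosages, MISSING = -1."""
        if not self.sites:
            return np.empty((0, len(self.samples)), dtype=np.int16)
        return np.stack([s.dosages for s in self.sites])

    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)


def read_vcf(path: str | Path, ploidy: int = 4) -> VcfData:
    """Read biallelic SNPs from a VCF (v4.2+) with polyploid genotypes.

    Dosage is the count of alternate alleles in the GT call; any missing
    allele makes the whole call missing. AD is parsed when present.
    Multiallelic records and indels are skipped and tallied in the skip
    report; records whose GT arity differs from ``ploidy`` are skipped
    with a warning.
    """
    sites: list[VariantSite] = []
    skipped: dict[str, int] = {}

    def _skip(reason: str) -> None:
        skipped[reason] = skipped.get(reason, 0) + 1

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                _skip("multiallelic" if len(alts) > 1 else "no_alt")
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt in (".", "*", "<NON_REF>"):
                _skip("indel")
                continue
            dosages = np.full(len(samples), MISSING, dtype=np.int16)
            depths = np.zeros((len(samples), 2), dtype=np.int64)
            any_ad = False
            bad_arity = False
            for i, name in enumerate(samples):
                call = rec.samples[name]
                gt = call.get("GT")
                if gt is not None and len(gt) not in (0, ploidy) and any(a is not None for a in gt):
                    bad_arity = True
                    break
                if gt is not None and len(gt) == ploidy and all(a is not None for a in gt):
                    dosages[i] = sum(1 for a in gt if a == 1)
                ad = call.get("AD")
                if ad is not None and len(ad) == 2 and all(x is not None for x in ad):
                    depths[i] = ad
                    any_ad = True
            if bad_arity:
                warnings.warn(
                    f"{rec.chrom}:{rec.pos}: GT arity != ploidy {ploidy}; record skipped",
                    stacklevel=2,
                )
                _skip("gt_arity")
                continue
            sites.append(
                VariantSite(rec.chrom, rec.pos, ref, alt, dosages, depths if any_ad else None)
            )
    return VcfData(sites, samples, skipped)


def write_vcf(
    data: VcfData,
    path: str | Path,
    layout: GenomeLayout | None = None,
    ploidy: int = 4,
) -> None:
    """Write sites back out as an uncompressed VCF v4.2.

    Dosage ``k`` becomes the unphased GT ``0/…/1`` with ``k`` alt alleles;
    missing dosage becomes ``./././.``. AD is emitted when depths exist.
    """
    header = pysam.VariantHeader()
    if layout is None:
        maxpos: dict[str, int] = {}
        for s in data.sites:
            maxpos[s.chrom] = max(maxpos.get(s.chrom, 0), s.pos)
        layout = GenomeLayout({c: p + 1 for c, p in maxpos.items()} or {"chr1": 1})
    for chrom, length in layout.lengths.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">')
    for name in data.samples:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in data.sites:
            rec = vf.new_record(
                contig=site.chrom, start=site.pos - 1, stop=site.pos, alleles=(site.ref, site.alt)
            )
            for i, name in enumerate(data.samples):
                d = int(site.dosages[i])
                if d == MISSING:
                    rec.samples[name]["GT"] = (None,) * ploidy
                else:
                    rec.samples[name]["GT"] = (0,) * (ploidy - d) + (1,) * d
                if site.depths is not None:
                    rec.samples[name]["AD"] = tuple(int(x) for x in site.depths[i])
            vf.write(rec)


def read_phenotypes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``sample<TAB>status`` table; status must be 0/1."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["sample", "status"])
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in phenotype table")
    status = df["status"].astype(int)
    if not status.isin([0, 1]).all():
        raise ValueError("phenotype status must be binary 0/1")
    return dict(zip(df["sample"].astype(str), status))


def write_phenotypes(phen: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, status in phen.items():
            fh.write(f"{name}\t{int(status)}\n")


def allele_frequency(ref_reads: int, alt_reads: int) -> float:
    """Alternate-allele read frequency alt/(ref+alt); NaN at zero depth."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        return math.nan
    return alt_reads / total


def call_dosage(alt_freq: float, depth: int, cfg: DosageFilterConfig = DosageFilterConfig()) -> int:
    """Call the tetraploid dosage nearest the observed alt read frequency.

    Returns :data:`MISSING` below the depth floor. The expected frequency
    of dosage k is k/4; ties between adjacent dosages break toward the
    lower dosage (conservative toward homozygous reference).
    """
    if not 0.0 <= alt_freq <= 1.0:
        raise ValueError("alt_freq must be in [0, 1]")
    if depth < cfg.min_dp:
        return MISSING
    return int(min(4, max(0, math.ceil(4.0 * alt_freq - 0.5))))


def site_filters(
    sites: Sequence[VariantSite], cfg: DosageFilterConfig = DosageFilterConfig()
) -> tuple[list[VariantSite], dict[str, int]]:
    """Drop sites with too many missing calls or too few minor-allele carriers.

    A sample "carries" the minor allele if its dosage includes at least one
    copy of it (alt-minor: dosage ≥ 1; ref-minor: dosage ≤ 3). Returns the
    retained sites and per-rule drop counts.
    """
    kept: list[VariantSite] = []
    drops = {"max_missing": 0, "min_minor": 0}
    for site in sites:
        d = site.dosages
        n = d.size
        missing = int((d == MISSING).sum())
        if n == 0 or missing / n > cfg.max_missing:
            drops["max_missing"] += 1
            continue
        called = d[d != MISSING]
        alt_copies = int(called.sum())
        ref_copies = int(4 * called.size - alt_copies)
        # ties count alt as minor
        if alt_copies <= ref_copies:
            carriers = int((called >= 1).sum())
        else:
            carriers = int((called <= 3).sum())
        if carriers < cfg.min_minor:
            drops["min_minor"] += 1
            continue
        kept.append(site)
    return kept, drops


def make_windows(layout: GenomeLayout, width: int = 100_000, step: int = 50_000) -> list[Window]:
    """Sliding windows over every chromosome of the layout.

    Starts at 0, step, 2·step, … while start < chromosome length; the end
    is clipped to the chromosome, so trailing partial windows are kept.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if step > width:
        raise ValueError("step must not exceed width")
    windows: list[Window] = []
    for chrom, length in layout.lengths.items():
        start = 0
        while start < length:
            windows.append(Window(chrom, start, min(start + width, length)))
            start += step
    return windows


def downsample_sites(
    sites: Sequence[VariantSite], n: int, seed: int | None = None
) -> list[VariantSite]:
    """Uniform random subsample of at most ``n`` sites, original order kept."""
    if n >= len(sites):
        return list(sites)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(sites), size=n, replace=False))
    return [sites[i] for i in idx]
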