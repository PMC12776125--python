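"""Family-based identity-by-descent homozygosity mapping.

Affected relatives that inherited the same recessive haplotype from a
common ancestor are homozygous across the shared segment, so the locus
lies where *all* affected samples show a run of windows nearly devoid of
heterozygous calls. In a tetraploid, "heterozygous" means alt dosage 1, 2
or 3 and "homozygous" means 0 or 4.

The per-window display metric is the excess-homozygosity score
``m_w = -(het count in window / median het count per window)``, which is 0
in fully homozygous windows and increasingly negative elsewhere.

Boundaries of the shared interval are refined with diagnostic SNPs —
sites homozygous for one allele in every affected sample and not
homozygous for that allele in any unaffected sample — scanning a fixed
distance (default 20 kb) on each side of a candidate breakpoint so that a
single discordant call cannot set a false border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bsa import interval_width
from .variants import MISSING, Window

__all__ = [
    "DiagnosticSNP",
    "BreakpointResult",
    "IntervalReport",
    "het_profile",
    "homozygosity_metric",
    "intervals_from_runs",
    "intersect_intervals",
    "shared_homozygous_intervals",
    "diagnostic_snps",
    "refine_breakpoint",
    "snap_borders",
    "final_interval",
]


@dataclass
class DiagnosticSNP:
    """Consistency of one site with shared affected homozygosity.

    ``allele`` is the allele every affected sample is homozygous for
    ('ref'/'alt'), or None when the affected samples do not share one.
    ``sample_status`` records, per unaffected sample, whether that sample
    satisfies the "no more than heterozygous" bound. ``consistent`` is the
    full rule: informative and satisfied by every sample.

    ``category`` separates the two ways a site can fail: sites where the
    *affected* samples are not homozygous for one shared allele
    ('affected_heterozygous') contradict an IBD interval covering them,
    whereas sites where only an unaffected sample is homozygous for the
    shared allele ('carrier_homozygous') are merely non-diagnostic — they
    carry no evidence against the interval and stay neutral during
    breakpoint refinement.
    """

    chrom: str
    pos: int
    allele: str | None
    consistent: bool
    sample_status: dict[str, bool]
    category: str = "diagnostic"  # | 'affected_heterozygous' | 'carrier_homozygous'


@dataclass
class BreakpointResult:
    """A refined interval border and its supporting evidence."""

    position: int
    confirmed: bool
    side: str  # 'left' or 'right' border of the interval
    n_consistent_inside: int
    n_inconsistent_outside: int
    supporting: list[int]  # positions of consistent SNPs inside the scan range


@dataclass
class IntervalReport:
    """A candidate interval with boundary provenance."""

    chrom: str
    left: int
    right: int
    left_provenance: BreakpointResult | None = None
    right_provenance: BreakpointResult | None = None

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError("crossed interval boundaries")

    @property
    def width_bp(self) -> int:
        return self.right - self.left

    @property
    def width_kb(self) -> int:
        return int(interval_width(self.left, self.right, "kb"))

    @property
    def width_mb(self) -> float:
        return float(interval_width(self.left, self.right, "Mb"))

    def contains(self, pos: int) -> bool:
        return self.left <= pos <= self.right


def het_profile(
    dosages: np.ndarray, positions: np.ndarray, windows: Sequence[Window], chrom: str
) -> np.ndarray:
    """Heterozygous-site count per window for one sample.

    ``dosages``: per-site alt dosage for the sample (MISSING ignored);
    ``positions``: matching 1-based bp. Returns counts aligned with
    ``windows``.
    """
    dosages = np.asarray(dosages)
    het = (dosages >= 1) & (dosages <= 3) & (dosages != MISSING)
    pos0 = np.sort(np.asarray(positions)[het] - 1)
    out = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        if w.chrom == chrom:
            out[i] = np.searchsorted(pos0, w.end) - np.searchsorted(pos0, w.start)
    return out


def homozygosity_metric(het_counts: np.ndarray) -> np.ndarray:
    """Excess-homozygosity score −(het count / median het count).

    The median is taken over all windows of the chromosome, zeros
    included; a zero median (near-fully homozygous sample) falls back to
    a normalizer of 1 so the score stays defined.
    """
    het_counts = np.asarray(het_counts, dtype=float)
    if het_counts.size == 0:
        raise ValueError("need at least one window")
    norm = float(np.median(het_counts))
    if norm == 0.0:
        norm = 1.0
    return -het_counts / norm


def intervals_from_runs(
    het_counts: np.ndarray, windows: Sequence[Window], h_max: int = 1
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive windows with het count ≤ h_max, as bp intervals.

    A run spans from the first window's start to the last window's end
    (0-based half-open). Windows are assumed ordered along one chromosome.
    """
    ok = np.asarray(het_counts) <= h_max
    out: list[tuple[int, int]] = []
    i = 0
    n = len(windows)
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1] and windows[j + 1].chrom == windows[i].chrom:
                j += 1
            out.append((windows[i].start, windows[j].end))
            i = j + 1
        else:
            i += 1
    return out


def intersect_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two sorted interval lists (half-open)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_homozygous_intervals(
    profiles: dict[str, np.ndarray], windows: Sequence[Window], h_max: int = 1
) -> list[tuple[int, int]]:
    """Homozygosity runs intersected across every affected sample."""
    if not profiles:
        raise ValueError("need at least one affected sample")
    result: list[tuple[int, int]] | None = None
    for counts in profiles.values():
        runs = intervals_from_runs(counts, windows, h_max)
        result = runs if result is None else intersect_intervals(result, runs)
    return result if result is not None else []


def diagnostic_snps(
    dosages: np.ndarray,
    positions: np.ndarray,
    samples: Sequence[str],
    affected: Sequence[str],
    unaffected: Sequence[str],
    chrom: str = "chr04",
) -> list[DiagnosticSNP]:
    """Evaluate every informative site against the diagnostic-SNP rule.

    ``dosages`` is (n_sites, n_samples). A site is informative when every
    required sample has a call. It is *consistent* (diagnostic) iff all
    affected samples are homozygous for the same allele A and no
    unaffected sample is homozygous for A (tetraploid reading of
    "homozygous in the affecteds, no more than heterozygous elsewhere").
    Non-informative sites are omitted.
    """
    if len(affected) == 0 or len(unaffected) == 0:
        raise ValueError("affected and unaffected sets must be non-empty")
    idx = {s: i for i, s in enumerate(samples)}
    ai = [idx[s] for s in affected]
    ui = [idx[s] for s in unaffected]
    out: list[DiagnosticSNP] = []
    aff = dosages[:, ai]
    unaff = dosages[:, ui]
    informative = ((aff != MISSING).all(axis=1)) & ((unaff != MISSING).all(axis=1))
    for k in np.flatnonzero(informative):
        arow = aff[k]
        urow = unaff[k]
        if (arow == 4).all():
            allele = "alt"
            status = {s: bool(urow[j] <= 3) for j, s in enumerate(unaffected)}
        elif (arow == 0).all():
            allele = "ref"
            status = {s: bool(urow[j] >= 1) for j, s in enumerate(unaffected)}
        else:
            out.append(
                DiagnosticSNP(
                    chrom, int(positions[k]), None, False, {}, "affected_heterozygous"
                )
            )
            continue
        ok = all(status.values())
        out.append(
            DiagnosticSNP(
                chrom,
                int(positions[k]),
                allele,
                ok,
                status,
                "diagnostic" if ok else "carrier_homozygous",
            )
        )
    return out


def refine_breakpoint(
    candidate: int,
    snps: Sequence[DiagnosticSNP],
    side: str,
    chrom_length: int,
    scan_bp: int = 20_000,
    n_confirm: int = 3,
    max_broken_inside: int = 1,
) -> BreakpointResult:
    """Confirm or move an interval border using diagnostic-SNP consistency.

    ``side`` names which border of the interval the candidate is ('left'
    means the interval lies to the right of it). A position is accepted
    when, within ``scan_bp`` of it, at least ``n_confirm`` SNPs on the
    interval side are consistent (diagnostic) and at least ``n_confirm``
    SNPs on the far side contradict shared affected homozygosity
    (category 'affected_heterozygous'; carrier-homozygous sites are
    neutral). The interval side must additionally be clean: more than
    ``max_broken_inside`` contradicting SNPs inside the scan window veto
    the candidate, which stops borders drifting into zones where a single
    sample's shared segment has already ended. A rejected candidate steps
    to the next informative SNP outward (away from the interval) and is
    re-evaluated; when no position confirms, the original candidate is
    returned flagged unconfirmed rather than moved.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    pos = np.asarray([s.pos for s in snps], dtype=np.int64)
    cons = np.asarray([s.consistent for s in snps], dtype=bool)
    broken = np.asarray([s.category == "affected_heterozygous" for s in snps], dtype=bool)
    order = np.argsort(pos)
    pos, cons, broken = pos[order], cons[order], broken[order]

    def evaluate(b: int) -> tuple[bool, int, int, list[int]]:
        if side == "left":
            inside = (pos > b) & (pos <= b + scan_bp)
            outside = (pos >= b - scan_bp) & (pos <= b)
        else:
            inside = (pos >= b - scan_bp) & (pos < b)
            outside = (pos >= b) & (pos <= b + scan_bp)
        n_in = int(cons[inside].sum())
        n_out = int(broken[outside].sum())
        n_broken_in = int(broken[inside].sum())
        support = [int(p) for p in pos[inside][cons[inside]]]
        ok = n_in >= n_confirm and n_out >= n_confirm and n_broken_in <= max_broken_inside
        return ok, n_in, n_out, support

    if side == "left":  # outward = smaller positions
        outward = pos[pos < candidate][::-1]
    else:
        outward = pos[pos > candidate]
    first = None
    for b in [candidate] + [int(p) for p in outward]:
        if not 0 <= b <= chrom_length:
            continue
        ok, n_in, n_out, support = evaluate(b)
        if first is None:
            first = (n_in, n_out, support)
        if ok:
            return BreakpointResult(b, True, side, n_in, n_out, support)
    n_in, n_out, support = first if first else (0, 0, [])
    return BreakpointResult(int(candidate), False, side, n_in, n_out, support)


def snap_borders(
    run: tuple[int, int], snps: Sequence[DiagnosticSNP], chrom_length: int
) -> tuple[int, int]:
    """Refine a window-quantized homozygosity run to SNP resolution.

    No site can contradict affected shared homozygosity strictly inside
    the true shared region, so the region's exact extent is bounded by
    the nearest 'affected_heterozygous' SNP on each side of an interior
    anchor. The anchor is the diagnostic SNP nearest the run midpoint
    (windowing can shift a run edge past the true region, so the raw
    midpoint alone is not trustworthy); without any diagnostic SNP the
    midpoint is used. Returns (left, right) border positions, clipped to
    the chromosome.
    """
    lo, hi = run
    mid = (lo + hi) // 2
    diag = np.asarray([s.pos for s in snps if s.consistent], dtype=np.int64)
    if diag.size:
        anchor = int(diag[np.argmin(np.abs(diag - mid))])
    else:
        anchor = mid
    broken = np.sort(
        np.asarray(
            [s.pos for s in snps if s.category == "affected_heterozygous"], dtype=np.int64
        )
    )
    left_candidates = broken[broken < anchor]
    right_candidates = broken[broken > anchor]
    left = int(left_candidates[-1]) if left_candidates.size else 0
    right = int(right_candidates[0]) if right_candidates.size else chrom_length
    return left, right


def final_interval(
    left: BreakpointResult, right: BreakpointResult, chrom: str = "chr04"
) -> IntervalReport:
    """Assemble the fine-mapped interval from two refined borders."""
    if left.position >= right.position:
        raise ValueError("crossed boundaries")
    return IntervalReport(chrom, left.position, right.position, left, right)


def metric_frame(
    profiles: dict[str, np.ndarray], windows: Sequence[Window]
) -> pd.DataFrame:
    """Long-format table of per-sample window het counts and metric values."""
    rows = []
    for sample, counts in profiles.items():
        metric = homozygosity_metric(counts)
        for w, c, m in zip(windows, counts, metric):
            rows.append((sample, w.chrom, w.start, w.end, int(c), float(m)))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "het_count", "metric"]
    )
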