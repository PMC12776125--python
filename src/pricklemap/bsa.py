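"""Bulked-segregant analysis for a recessive locus in a tetraploid self.

Two DNA pools are sequenced: a mutant bulk of affected (prickleless)
progeny and a control bulk of unaffected (prickled) siblings. At a marker
tightly linked in coupling to the recessive allele the mutant bulk is
nearly fixed for the causal allele while the control bulk is not, so
sites are kept when

    mutant-bulk causal AF >= theta_mut   and   control-bulk causal AF <= theta_wt

and the count of passing sites per sliding window is the scan statistic.
Allele frequencies come from pooled read counts, never genotype calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .simulate import BulkReadCounts
from .variants import Window

__all__ = [
    "BsaThresholds",
    "EnrichedInterval",
    "recessive_filter",
    "polarize",
    "passing_mask",
    "scan",
    "call_enriched_interval",
    "interval_width",
    "bulk_counts_from_frame",
]


@dataclass(frozen=True)
class BsaThresholds:
    """Recessive-inheritance allele-frequency filter bounds.

    theta_mut: minimum causal-allele frequency in the mutant bulk.
    theta_wt: maximum causal-allele frequency in the control bulk.
    min_depth: minimum pooled depth per bulk for a site to be evaluated.
    """

    theta_mut: float = 0.95
    theta_wt: float = 0.85
    min_depth: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_wt < self.theta_mut <= 1.0:
            raise ValueError("require 0 <= theta_wt < theta_mut <= 1")


@dataclass
class EnrichedInterval:
    """Contiguous run of high-count windows around the scan maximum."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    peak_count: int
    threshold: float
    window_indices: tuple[int, int]  # first, last window index of the run

    @property
    def width_bp(self) -> int:
        return self.end - self.start

    def contains(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


def recessive_filter(mut_af: float, wt_af: float, thr: BsaThresholds = BsaThresholds()) -> bool:
    """Pass iff the site segregates like a recessive causal allele.

    Sites with a missing frequency in either bulk fail.
    """
    if math.isnan(mut_af) or math.isnan(wt_af):
        return False
    return mut_af >= thr.theta_mut and wt_af <= thr.theta_wt


def polarize(
    mut_ref: np.ndarray,
    mut_alt: np.ndarray,
    mode: Literal["alt", "auto"] = "alt",
) -> np.ndarray:
    """Candidate-causal allele orientation per site ('ref' or 'alt').

    The reference genome of a mapping run usually carries the dominant
    functional allele, making the causal allele the alt allele ('alt'
    mode, the default). 'auto' instead picks, per site, the allele at
    higher frequency in the mutant bulk (ties → alt).
    """
    n = len(mut_ref)
    if mode == "alt":
        return np.full(n, "alt", dtype=object)
    mut_ref = np.asarray(mut_ref, dtype=float)
    mut_alt = np.asarray(mut_alt, dtype=float)
    return np.where(mut_ref > mut_alt, "ref", "alt").astype(object)


def passing_mask(
    counts: BulkReadCounts,
    thr: BsaThresholds = BsaThresholds(),
    orientation_mode: Literal["alt", "auto"] = "alt",
) -> np.ndarray:
    """Boolean mask of sites passing depth + recessive-inheritance filters."""
    mut_tot = counts.mut_ref + counts.mut_alt
    wt_tot = counts.wt_ref + counts.wt_alt
    deep = (mut_tot >= thr.min_depth) & (wt_tot >= thr.min_depth)
    orient = polarize(counts.mut_ref, counts.mut_alt, orientation_mode)
    with np.errstate(invalid="ignore"):
        mut_af = np.where(mut_tot > 0, counts.mut_alt / np.maximum(mut_tot, 1), np.nan)
        wt_af = np.where(wt_tot > 0, counts.wt_alt / np.maximum(wt_tot, 1), np.nan)
    flip = orient == "ref"
    mut_af = np.where(flip, 1.0 - mut_af, mut_af)
    wt_af = np.where(flip, 1.0 - wt_af, wt_af)
    return deep & (mut_af >= thr.theta_mut) & (wt_af <= thr.theta_wt)


def scan(
    counts: BulkReadCounts,
    windows: Sequence[Window],
    thr: BsaThresholds = BsaThresholds(),
    orientation_mode: Literal["alt", "auto"] = "alt",
) -> pd.DataFrame:
    """Passing-variant count per sliding window.

    A passing variant contributes to *every* window containing its
    position, so overlapping windows double-count by design (that is the
    plotted statistic). Returns a frame ``chrom, start, end, count``
    aligned with ``windows``.
    """
    mask = passing_mask(counts, thr, orientation_mode)
    pos0 = np.sort(counts.positions[mask] - 1)  # 0-based for half-open windows
    rows = []
    for w in windows:
        if w.chrom != counts.chrom:
            n = 0
        else:
            n = int(np.searchsorted(pos0, w.end) - np.searchsorted(pos0, w.start))
        rows.append((w.chrom, w.start, w.end, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def call_enriched_interval(
    profile: pd.DataFrame,
    fraction: float = 0.2,
    min_count: int = 2,
    max_gap: int = 8,
) -> EnrichedInterval | None:
    """Merge the cluster of high-count windows around the scan maximum.

    Windows with count >= max(min_count, fraction · global max) are marked;
    the run of marked windows containing the global maximum (leftmost on
    ties) is merged, tolerating gaps of up to ``max_gap`` consecutive
    unmarked windows inside the cluster. The gap tolerance matters at
    realistic marker densities, where the enriched plateau holds only a
    few passing variants per window and strict contiguity would shatter
    it into noise islands (``max_gap=0`` recovers the strict rule). The
    interval spans the first to the last *marked* window of the cluster.
    Returns ``None`` when no window reaches the mark ("no signal").
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    counts = profile["count"].to_numpy()
    chroms = profile["chrom"].to_numpy()
    peak = int(counts.max())
    threshold = max(float(min_count), fraction * peak)
    marked = counts >= threshold
    if not marked.any():
        return None
    imax = int(counts.argmax())  # leftmost global max
    same = chroms == chroms[imax]
    lo = imax
    i = imax - 1
    gap = 0
    while i >= 0 and same[i] and gap <= max_gap:
        if marked[i]:
            lo = i
            gap = 0
        else:
            gap += 1
        i -= 1
    hi = imax
    i = imax + 1
    gap = 0
    while i < len(counts) and same[i] and gap <= max_gap:
        if marked[i]:
            hi = i
            gap = 0
        else:
            gap += 1
        i += 1
    return EnrichedInterval(
        chrom=str(chroms[imax]),
        start=int(profile["start"].iat[lo]),
        end=int(profile["end"].iat[hi]),
        peak_count=peak,
        threshold=threshold,
        window_indices=(lo, hi),
    )


def interval_width(start: int, end: int, unit: Literal["bp", "kb", "Mb"] = "bp") -> float | int:
    """Interval width in bp, floored kb, or Mb.

    The kb rendering floors (a 324,731 bp interval is "324 kb"); the Mb
    rendering is exact division.
    """
    if end <= start:
        raise ValueError("end must exceed start")
    span = end - start
    if unit == "bp":
        return span
    if unit == "kb":
        return span // 1_000
    if unit == "Mb":
        return span / 1_000_000
    raise ValueError(f"unknown unit {unit!r}")


def bulk_counts_from_frame(df: pd.DataFrame) -> BulkReadCounts:
    """Build bulk counts from a ``chrom,pos,mut_ref,mut_alt,wt_ref,wt_alt`` table."""
    required = ["chrom", "pos", "mut_ref", "mut_alt", "wt_ref", "wt_alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"bulk count table missing columns: {missing}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("one chromosome per bulk-count table")
    order = np.argsort(df["pos"].to_numpy(), kind="stable")
    df = df.iloc[order]
    return BulkReadCounts(
        positions=df["pos"].to_numpy(np.int64),
        mut_ref=df["mut_ref"].to_numpy(np.int64),
        mut_alt=df["mut_alt"].to_numpy(np.int64),
        wt_ref=df["wt_ref"].to_numpy(np.int64),
        wt_alt=df["wt_alt"].to_numpy(np.int64),
        chrom=str(chroms[0]),
    )
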