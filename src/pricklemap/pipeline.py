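"""High-level mapping pipelines tying the stages together.

Each function here runs one of the mapping strategies end-to-end on
in-memory data; the CLI and the analysis drivers are thin wrappers over
these.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import bsa as bsa_mod
from . import ibd as ibd_mod
from .simulate import BulkReadCounts, ReadModel, SimConfig, SimPopulation, make_founder, self_cross, simulate_reads
from .variants import GenomeLayout, make_windows

__all__ = [
    "BsaResult",
    "IbdResult",
    "run_bsa",
    "run_ibd",
    "simulate_bsa_family",
]


@dataclass
class BsaResult:
    profile: pd.DataFrame
    interval: bsa_mod.EnrichedInterval | None
    thresholds: bsa_mod.BsaThresholds
    n_passing: int


@dataclass
class IbdResult:
    metric: pd.DataFrame
    shared: list[tuple[int, int]]
    interval: ibd_mod.IntervalReport | None
    n_diagnostic: int


def run_bsa(
    counts: BulkReadCounts,
    layout: GenomeLayout,
    width: int = 100_000,
    step: int = 50_000,
    thresholds: bsa_mod.BsaThresholds = bsa_mod.BsaThresholds(),
    orientation_mode: str = "alt",
    fraction: float = 0.2,
    min_count: int = 2,
    max_gap: int = 8,
) -> BsaResult:
    """Recessive-filter the bulk counts, window-scan, and call the peak interval."""
    windows = make_windows(layout, width, step)
    profile = bsa_mod.scan(counts, windows, thresholds, orientation_mode)  # type: ignore[arg-type]
    interval = bsa_mod.call_enriched_interval(profile, fraction, min_count, max_gap)
    n_pass = int(bsa_mod.passing_mask(counts, thresholds, orientation_mode).sum())  # type: ignore[arg-type]
    return BsaResult(profile, interval, thresholds, n_pass)


def run_ibd(
    dosages: np.ndarray,
    positions: np.ndarray,
    samples: Sequence[str],
    affected: Sequence[str],
    unaffected: Sequence[str],
    layout: GenomeLayout,
    chrom: str,
    width: int = 100_000,
    step: int = 50_000,
    h_max: int = 1,
    scan_bp: int = 20_000,
    n_confirm: int = 3,
) -> IbdResult:
    """Shared-homozygosity mapping with diagnostic-SNP breakpoint refinement.

    Steps: per-affected window het profiles → runs of homozygous windows →
    intersection across affecteds → widest shared run as candidate →
    borders snapped to SNP resolution and confirmed within ``scan_bp`` →
    final report with boundary provenance.
    """
    if len(affected) == 0:
        raise ValueError("need at least one affected sample")
    windows = make_windows(layout, width, step)
    idx = {s: i for i, s in enumerate(samples)}
    profiles = {
        s: ibd_mod.het_profile(dosages[:, idx[s]], positions, windows, chrom) for s in affected
    }
    metric = ibd_mod.metric_frame(profiles, windows)
    shared = ibd_mod.shared_homozygous_intervals(profiles, windows, h_max)
    snps = ibd_mod.diagnostic_snps(dosages, positions, samples, affected, unaffected, chrom)
    n_diag = sum(1 for s in snps if s.consistent)
    if not shared:
        return IbdResult(metric, shared, None, n_diag)

    cons_pos = np.sort(np.asarray([s.pos for s in snps if s.consistent], dtype=np.int64))

    def diag_inside(iv: tuple[int, int]) -> int:
        # interval is 0-based half-open; SNP positions 1-based
        return int(
            np.searchsorted(cons_pos, iv[1], "right") - np.searchsorted(cons_pos, iv[0] + 1, "left")
        )

    # candidate = widest shared run (the causal region's sharing is enforced by
    # descent, incidental pockets of agreement are short); diagnostic support
    # breaks ties
    best = max(shared, key=lambda iv: (iv[1] - iv[0], diag_inside(iv)))
    chrom_length = layout[chrom]
    snap_l, snap_r = ibd_mod.snap_borders(best, snps, chrom_length)
    left = ibd_mod.refine_breakpoint(snap_l, snps, "left", chrom_length, scan_bp, n_confirm)
    right = ibd_mod.refine_breakpoint(snap_r, snps, "right", chrom_length, scan_bp, n_confirm)
    lpos, rpos = left.position, right.position
    if lpos >= rpos:
        # degenerate refinement; fall back to the unrefined window run
        report = ibd_mod.IntervalReport(chrom, best[0], best[1], None, None)
    else:
        report = ibd_mod.final_interval(left, right, chrom)
    return IbdResult(metric, shared, report, n_diag)


def simulate_bsa_family(
    cfg: SimConfig,
    bulk_depth: float = 300.0,
    error: float = 0.005,
    quota: tuple[int, int] | None = None,
    seed: int | None = None,
) -> tuple[SimPopulation, BulkReadCounts]:
    """Self the founder and sequence phenotype bulks to ~``bulk_depth`` each.

    Per-individual mean depth is bulk_depth / bulk size, so each pooled
    bulk reaches approximately the requested coverage.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    founder = make_founder(cfg, rng)
    pop = self_cross(founder, rng=rng, quota=quota)
    mut = pop.affected_names()
    wt = pop.unaffected_names()
    if not mut or not wt:
        raise ValueError("cross produced an empty phenotype bulk")
    depths = {n: bulk_depth / len(mut) for n in mut}
    depths.update({n: bulk_depth / len(wt) for n in wt})
    model = ReadModel(depth=1.0, error=error, seed=seed)
    counts = simulate_reads(pop, model, bulks=(mut, wt), depths=depths, rng=rng)
    assert isinstance(counts, BulkReadCounts)
    return pop, counts
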