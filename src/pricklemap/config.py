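"""Run configuration: one home per tunable parameter, YAML round trip.

Defaults follow the mapping protocol this package implements: 100 kb
windows with a 50 kb step; recessive-filter bounds 0.95 / 0.85; dosage
filters min DP 2, max missing 0.05, min minor-allele carriers 5; 20 kb
breakpoint scan; genome-wide significance 5e-8.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # window engine
    window_size: int = 100_000
    step: int = 50_000
    # BSA recessive filter
    af_mut_min: float = 0.95
    af_wt_max: float = 0.85
    min_bulk_depth: int = 10
    interval_fraction: float = 0.2
    interval_min_count: int = 2
    interval_max_gap: int = 8
    orientation_mode: str = "alt"  # causal-allele polarity: 'alt' | 'auto'
    # dosage filters
    min_dp: int = 2
    max_missing: float = 0.05
    min_minor: int = 5
    # IBD mapping
    h_max: int = 1
    scan_kb: int = 20
    n_confirm: int = 3
    # association
    orientation: str = "ref"  # 1-dom orientation: 'ref' | 'alt'
    p_threshold: float = 5e-8
    # simulator
    chrom: str = "chr04"
    chrom_length: int = 40_000_000
    genetic_length: float = 2.0
    n_snps: int = 20_000
    causal_pos: int = 33_700_000
    parent_dosage: int = 3
    alpha_dr: float = 0.0
    n_progeny: int = 97
    founder_het: float = 0.5
    mean_depth: float = 10.0
    error_rate: float = 0.005
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML key-value config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
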