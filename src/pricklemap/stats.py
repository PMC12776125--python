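"""Dominance-coded association scan and cross/contingency statistics.

The association model is the tetraploid "1-dom" coding: each sample's
dosage collapses to carrier / non-carrier of the dominant allele
(ref-dominant by default, since a prickled reference genome carries the
dominant functional allele), and each marker is tested against the binary
trait with a two-sided exact test on the resulting 2×2 table. Bonferroni
adjustment and the conventional genome-wide line p = 5e-8 are both
reported.

Also here: the chi-square goodness-of-fit test of observed segregation
ratios against tetrasomic expectations for a self (e.g. 1 affected : 3
unaffected for a triplex parent), and Cramer's V for r×c contingency
tables of categorical trait codings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import gamete_dosage_pmf
from .variants import MISSING

__all__ = [
    "ScanRecord",
    "SegregationResult",
    "dom_code",
    "marker_test",
    "genome_scan",
    "segregation_test",
    "cramers_v",
    "GENOME_WIDE_P",
]

GENOME_WIDE_P = 5e-8


@dataclass
class ScanRecord:
    """Per-marker association result."""

    chrom: str
    pos: int
    orientation: str
    p: float  # NaN when the table is degenerate
    p_bonf: float
    neglog10p: float
    reason: str = ""


@dataclass
class SegregationResult:
    """Goodness of fit of observed phenotype counts to a selfing ratio."""

    observed: tuple[int, int]
    expected: tuple[float, float]
    expected_fraction: float
    chi2: float | None
    df: int | None
    p: float | None
    consistent: bool  # only meaningful on the degenerate (0/1 fraction) path


def dom_code(
    dosages: np.ndarray, orientation: Literal["ref", "alt"] = "ref"
) -> np.ndarray:
    """Collapse dosages to carrier indicators under a 1-dom coding.

    ref-dominant: carrier iff the sample holds ≥1 reference allele
    (alt dosage ≤ 3). alt-dominant: carrier iff alt dosage ≥ 1.
    Missing dosage (MISSING) propagates as MISSING.
    """
    dosages = np.asarray(dosages)
    if orientation == "ref":
        coded = (dosages <= 3).astype(np.int16)
    elif orientation == "alt":
        coded = (dosages >= 1).astype(np.int16)
    else:
        raise ValueError("orientation must be 'ref' or 'alt'")
    return np.where(dosages == MISSING, MISSING, coded)


def marker_test(carrier: np.ndarray, affected: np.ndarray) -> tuple[float, str]:
    """Two-sided exact test of carrier status against the binary trait.

    Sums, under the hypergeometric null with the observed margins, the
    probabilities of all 2×2 tables no more probable than the observed
    one (the standard two-sided exact 2×2 test). Degenerate margins give
    (NaN, reason) rather than an exception.
    """
    carrier = np.asarray(carrier)
    affected = np.asarray(affected)
    keep = (carrier != MISSING) & (affected != MISSING)
    c = carrier[keep].astype(bool)
    a = affected[keep].astype(bool)
    n = int(keep.sum())
    if n < 2:
        return float("nan"), "fewer than 2 informative samples"
    n_carrier = int(c.sum())
    n_affected = int(a.sum())
    if n_carrier in (0, n):
        return float("nan"), "all samples identical for marker coding"
    if n_affected in (0, n):
        return float("nan"), "all samples identical for phenotype"
    observed = int((c & a).sum())
    lo = max(0, n_carrier + n_affected - n)
    hi = min(n_carrier, n_affected)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, n_affected, n_carrier)
    p_obs = pmf[observed - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0), ""


def genome_scan(
    dosages: np.ndarray,
    positions: np.ndarray,
    samples: Sequence[str],
    phenotypes: dict[str, int],
    orientation: Literal["ref", "alt"] = "ref",
    chrom: str = "chr04",
    p_star: float = GENOME_WIDE_P,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact-test association scan over pre-filtered sites.

    Returns (all records, significant subset with raw p < p_star), both
    sorted by position, with Bonferroni-adjusted p over the number of
    testable sites.
    """
    affected = np.asarray([phenotypes.get(s, MISSING) for s in samples])
    order = np.argsort(np.asarray(positions), kind="stable")
    records: list[ScanRecord] = []
    for k in order:
        coding = dom_code(dosages[k], orientation)
        p, reason = marker_test(coding, affected)
        records.append(
            ScanRecord(chrom, int(positions[k]), f"{orientation}-dominant", p, 1.0, 0.0, reason)
        )
    m = sum(1 for r in records if not np.isnan(r.p))
    for r in records:
        if not np.isnan(r.p):
            r.p_bonf = min(1.0, r.p * m)
            r.neglog10p = float(-np.log10(r.p)) if r.p > 0 else float("inf")
        else:
            r.p_bonf = float("nan")
            r.neglog10p = float("nan")
    df = pd.DataFrame(
        [
            (r.chrom, r.pos, r.orientation, r.p, r.p_bonf, r.neglog10p, r.reason)
            for r in records
        ],
        columns=["chrom", "pos", "orientation", "p", "p_bonf", "neglog10p", "reason"],
    )
    sig = df[df["p"] < p_star].reset_index(drop=True)
    return df, sig


def segregation_test(
    observed: tuple[int, int], parent_dosage: int = 3, alpha: float = 0.0
) -> SegregationResult:
    """Chi-square test of observed affected:unaffected counts in a self.

    The affected class is the nulliplex-functional (quadriplex causal)
    class, so its expected fraction is the squared probability that a
    gamete carries two causal copies. A triplex parent at alpha = 0 gives
    the classic 1:3 tetrasomic ratio. Degenerate expectations (fraction
    0 or 1) skip the chi-square and just report consistency.
    """
    n_aff, n_un = observed
    if n_aff < 0 or n_un < 0 or n_aff + n_un == 0:
        raise ValueError("need non-negative counts with positive total")
    frac = gamete_dosage_pmf(parent_dosage, alpha)[2] ** 2
    total = n_aff + n_un
    expected = (frac * total, (1 - frac) * total)
    if frac in (0.0, 1.0):
        consistent = (n_aff == 0) if frac == 0.0 else (n_un == 0)
        return SegregationResult(observed, expected, frac, None, None, None, consistent)
    chi2 = (n_aff - expected[0]) ** 2 / expected[0] + (n_un - expected[1]) ** 2 / expected[1]
    p = float(sps.chi2.sf(chi2, df=1))
    return SegregationResult(observed, expected, frac, float(chi2), 1, p, True)


def cramers_v(
    table: np.ndarray | pd.DataFrame, bias_corrected: bool = False
) -> tuple[float, float]:
    """(chi-square, Cramer's V) for an r×c contingency table.

    Pearson chi-square with margin-derived expectations, no continuity
    correction; V = sqrt(chi2 / (N · (min(r, c) − 1))). Zero rows or
    columns are dropped with a warning before computation. The optional
    bias-corrected variant applies the Bergsma small-sample correction.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        import warnings

        warnings.warn("dropping zero-margin rows/columns before chi-square", stacklevel=2)
        arr = arr[row_ok][:, col_ok]
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("table degenerate after dropping zero margins")
    n = arr.sum()
    if n <= 0:
        raise ValueError("empty table")
    chi2 = float(sps.chi2_contingency(arr, correction=False).statistic)
    r, c = arr.shape
    if bias_corrected:
        phi2 = chi2 / n
        phi2c = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
        rc = r - (r - 1) ** 2 / (n - 1)
        cc = c - (c - 1) ** 2 / (n - 1)
        v = float(np.sqrt(phi2c / max(min(rc, cc) - 1, 1e-12)))
    else:
        v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return chi2, v
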