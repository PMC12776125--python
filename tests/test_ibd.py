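"""IBD homozygosity mapping: windows, metric, intervals, diagnostics."""

import numpy as np
import pytest

from pricklemap.ibd import (
    DiagnosticSNP,
    IntervalReport,
    diagnostic_snps,
    final_interval,
    het_profile,
    homozygosity_metric,
    intersect_intervals,
    intervals_from_runs,
    refine_breakpoint,
    shared_homozygous_intervals,
    snap_borders,
)
from pricklemap.variants import MISSING, GenomeLayout, make_windows

WINDOWS_200K = make_windows(GenomeLayout({"c": 200_000}), 100_000, 50_000)


class TestHetProfile:
    def test_all_homozygous_gives_zeros(self):
        counts = het_profile(
            np.array([0, 4, 0, 4]), np.array([10_001, 60_001, 120_001, 170_001]),
            WINDOWS_200K, "c",
        )
        assert counts.tolist() == [0, 0, 0, 0]

    def test_membership_example(self):
        counts = het_profile(
            np.array([2, 4, 1]), np.array([10_001, 60_001, 120_001]), WINDOWS_200K, "c"
        )
        assert counts.tolist() == [1, 1, 1, 0]

    def test_missing_calls_excluded(self):
        counts = het_profile(
            np.array([MISSING, MISSING]), np.array([10_001, 60_001]), WINDOWS_200K, "c"
        )
        assert counts.tolist() == [0, 0, 0, 0]


class TestHomozygosityMetric:
    def test_median_normalized_example(self):
        assert homozygosity_metric(np.array([2, 4, 6])).tolist() == [-0.5, -1.0, -1.5]

    def test_degenerate_median_floors_to_one(self):
        assert homozygosity_metric(np.array([0, 0, 0])).tolist() == [0.0, 0.0, 0.0]

    def test_single_window_is_own_median(self):
        assert homozygosity_metric(np.array([5])).tolist() == [-1.0]

    def test_scale_invariant_to_doubling(self):
        counts = np.array([1, 3, 0, 7, 2])
        assert np.allclose(homozygosity_metric(counts), homozygosity_metric(2 * counts))

    def test_zero_exactly_when_no_hets(self):
        m = homozygosity_metric(np.array([0, 3, 0, 5]))
        assert (m == 0).tolist() == [True, False, True, False]


class TestSharedIntervals:
    def test_run_extraction(self):
        # windows: [0,100k) [50k,150k) [100k,200k) [150k,200k); the two
        # middle windows qualify, and the run spans their union
        runs = intervals_from_runs(np.array([5, 0, 0, 5]), WINDOWS_200K, h_max=0)
        assert runs == [(50_000, 200_000)]

    def test_disjoint_runs_empty_intersection(self):
        a = {"s1": np.array([0, 5, 5, 5])}  # run: first window only
        b = {"s2": np.array([5, 5, 5, 0])}  # run: last window only
        assert shared_homozygous_intervals({**a, **b}, WINDOWS_200K, h_max=0) == []

    def test_identical_profiles_idempotent(self):
        counts = np.array([5, 0, 0, 5])
        one = shared_homozygous_intervals({"s1": counts}, WINDOWS_200K, h_max=0)
        two = shared_homozygous_intervals(
            {"s1": counts, "s2": counts.copy()}, WINDOWS_200K, h_max=0
        )
        assert one == two == [(50_000, 200_000)]

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            shared_homozygous_intervals({}, WINDOWS_200K)

    def test_intersection_monotone_in_samples(self):
        rng = np.random.default_rng(31)
        windows = make_windows(GenomeLayout({"c": 2_000_000}), 100_000, 50_000)
        profiles = {
            f"s{i}": rng.poisson(1.2, size=len(windows)) for i in range(4)
        }
        full = shared_homozygous_intervals(profiles, windows)
        sub = shared_homozygous_intervals(
            {k: profiles[k] for k in list(profiles)[:3]}, windows
        )
        # every point of the k+1-sample result lies in the k-sample result
        for lo, hi in full:
            assert any(a <= lo and hi <= b for a, b in sub) or intersect_intervals(
                [(lo, hi)], sub
            ) == [(lo, hi)]


def brute_force_diagnostic(dosages, affected_idx, unaffected_idx):
    """Oracle: literal per-site rule check."""
    out = []
    for row in dosages:
        aff = [row[i] for i in affected_idx]
        un = [row[i] for i in unaffected_idx]
        if any(d == MISSING for d in aff + un):
            out.append(None)  # not informative
        elif all(d == 4 for d in aff):
            out.append(all(d <= 3 for d in un))
        elif all(d == 0 for d in aff):
            out.append(all(d >= 1 for d in un))
        else:
            out.append(False)
    return out


class TestDiagnosticSnps:
    samples = ["a1", "a2", "u1", "u2", "u3"]
    affected = ["a1", "a2"]
    unaffected = ["u1", "u2", "u3"]

    def _run(self, rows):
        dosages = np.array(rows)
        positions = np.arange(1, len(rows) + 1) * 100
        return diagnostic_snps(
            dosages, positions, self.samples, self.affected, self.unaffected, "c"
        )

    def test_qualifying_site(self):
        (snp,) = self._run([[4, 4, 3, 2, 1]])
        assert snp.consistent and snp.allele == "alt" and snp.category == "diagnostic"

    def test_homozygous_unaffected_fails(self):
        (snp,) = self._run([[4, 4, 4, 2, 1]])
        assert not snp.consistent and snp.category == "carrier_homozygous"
        assert snp.sample_status == {"u1": False, "u2": True, "u3": True}

    def test_split_affecteds_fail(self):
        (snp,) = self._run([[0, 4, 2, 2, 2]])
        assert not snp.consistent and snp.category == "affected_heterozygous"

    def test_shared_ref_allele_qualifies(self):
        (snp,) = self._run([[0, 0, 1, 2, 3]])
        assert snp.consistent and snp.allele == "ref"

    def test_missing_disqualifies(self):
        snps = self._run([[4, MISSING, 3, 2, 1]])
        assert snps == []  # non-informative sites omitted

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(37)
        n = 5_000
        dosages = rng.integers(-1, 5, size=(n, 5)).astype(np.int16)
        positions = np.arange(1, n + 1) * 10
        got = diagnostic_snps(
            dosages, positions, self.samples, self.affected, self.unaffected, "c"
        )
        want = brute_force_diagnostic(dosages, [0, 1], [2, 3, 4])
        got_by_pos = {s.pos: s.consistent for s in got}
        for pos, expected in zip(positions, want):
            if expected is None:
                assert pos not in got_by_pos
            else:
                assert got_by_pos[pos] == expected

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_snps(np.zeros((1, 5)), np.array([1]), self.samples, [], self.unaffected)


def _snp(pos, category):
    return DiagnosticSNP("c", pos, "alt", category == "diagnostic", {}, category)


class TestRefineBreakpoint:
    def test_confirmed_with_three_each_side(self):
        snps = [_snp(p, "diagnostic") for p in (10_500, 11_000, 12_000)]
        snps += [_snp(p, "affected_heterozygous") for p in (8_000, 9_000, 9_500)]
        res = refine_breakpoint(10_000, snps, "left", 1_000_000)
        assert res.confirmed and res.position == 10_000
        assert res.supporting == [10_500, 11_000, 12_000]

    def test_below_n_confirm_unconfirmed(self):
        snps = [_snp(9_000, "affected_heterozygous")]
        snps += [_snp(p, "diagnostic") for p in (10_500, 11_000, 12_000)]
        res = refine_breakpoint(10_000, snps, "left", 1_000_000)
        assert not res.confirmed and res.position == 10_000

    def test_no_snps_in_range_unconfirmed(self):
        snps = [_snp(500_000, "diagnostic")]
        res = refine_breakpoint(10_000, snps, "left", 1_000_000)
        assert not res.confirmed

    def test_outward_walk_finds_border(self):
        # candidate sits 5 kb inside the true region; stepping outward (left)
        # reaches a position with contradicting sites beyond it
        snps = [_snp(p, "diagnostic") for p in range(10_200, 30_000, 400)]
        snps += [_snp(p, "affected_heterozygous") for p in range(1_000, 10_000, 400)]
        res = refine_breakpoint(15_000, snps, "left", 1_000_000)
        assert res.confirmed and res.position <= 15_000

    def test_carrier_homozygous_sites_are_neutral(self):
        snps = [_snp(p, "diagnostic") for p in (10_500, 11_000, 12_000)]
        snps += [_snp(p, "carrier_homozygous") for p in (8_000, 9_000, 9_500)]
        res = refine_breakpoint(10_000, snps, "left", 1_000_000)
        assert not res.confirmed  # carrier-homozygous is not contrary evidence

    def test_broken_sites_inside_veto(self):
        snps = [_snp(p, "diagnostic") for p in (10_500, 11_000, 12_000)]
        snps += [_snp(p, "affected_heterozygous") for p in (8_000, 9_000, 9_500)]
        snps += [_snp(p, "affected_heterozygous") for p in (13_000, 14_000)]
        res = refine_breakpoint(10_000, snps, "left", 1_000_000, max_broken_inside=1)
        assert not (res.confirmed and res.position == 10_000)


class TestSnapBorders:
    def test_snaps_to_flanking_broken_sites(self):
        snps = [_snp(p, "diagnostic") for p in (10_000, 12_000, 14_000)]
        snps += [_snp(p, "affected_heterozygous") for p in (7_000, 18_000)]
        left, right = snap_borders((9_000, 15_000), snps, 1_000_000)
        assert (left, right) == (7_000, 18_000)

    def test_clips_to_chromosome_without_flanks(self):
        snps = [_snp(12_000, "diagnostic")]
        assert snap_borders((9_000, 15_000), snps, 1_000_000) == (0, 1_000_000)


class TestFinalInterval:
    def _bp(self, pos, side):
        from pricklemap.ibd import BreakpointResult

        return BreakpointResult(pos, True, side, 3, 3, [])

    def test_reported_ibd_widths(self):
        report = final_interval(self._bp(30_482_969, "left"), self._bp(30_807_700, "right"))
        assert report.width_bp == 324_731
        assert report.width_kb == 324

    def test_reported_bsa_widths(self):
        report = final_interval(self._bp(32_950_000, "left"), self._bp(34_250_000, "right"))
        assert report.width_mb == 1.3

    def test_small_interval_floors_to_zero_kb(self):
        report = final_interval(self._bp(100, "left"), self._bp(200, "right"))
        assert report.width_bp == 100 and report.width_kb == 0

    def test_crossed_boundaries_rejected(self):
        with pytest.raises(ValueError):
            final_interval(self._bp(200, "left"), self._bp(100, "right"))

    def test_interval_report_invariants(self):
        with pytest.raises(ValueError):
            IntervalReport("c", 10, 10)
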