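"""Site collapsing, normalization, moving-median background, Poisson test,
summit calling / extension / merging, and the repeat-support rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ragscan.genome import RestrictionMap
from ragscan.peaks3c import (
    SiteStats,
    call_peaks_single,
    collapse_to_sites,
    poisson_upper_p,
    preprocess_3c,
    robust_peaks,
    rolling_median_lambda,
    site_stats_from_counts,
)
from ragscan.types import BaitSpec, JunctionLibrary, JunctionRecord, PeakRegion


def _rec(pos, chrom="chr1"):
    return JunctionRecord("lib", chrom, pos, "+", "bait", f"r{pos}")


BAIT = BaitSpec("bait", "chr1", 50_000, "+", (50_060, 50_200))


class TestCollapseToSites:
    RMAP = RestrictionMap({"chr1": [100, 130, 500]})

    def test_junction_within_10bp_assigned(self):
        counts, discarded = collapse_to_sites([_rec(103)], self.RMAP)
        assert counts["chr1"] == {100: 1} and discarded == 0

    def test_junction_beyond_10bp_discarded(self):
        counts, discarded = collapse_to_sites([_rec(511)], self.RMAP)
        assert not counts and discarded == 1

    def test_exact_tie_goes_to_leftmost_site(self):
        # position 115 is 15 bp from several... use sites 100 and 130: 115 is
        # 15 from both (beyond max); use 105/125 -> tie at 10 each: no such
        # sites, so craft a map with a true 10-bp tie
        rmap = RestrictionMap({"chr1": [100, 120]})
        counts, discarded = collapse_to_sites([_rec(110)], rmap, max_dist=10)
        assert counts["chr1"] == {100: 1}

    def test_assigned_plus_discarded_is_total(self):
        rng = np.random.default_rng(0)
        recs = [_rec(int(p)) for p in rng.integers(0, 600, 300)]
        counts, discarded = collapse_to_sites(recs, self.RMAP)
        assert sum(counts.get("chr1", {}).values()) + discarded == 300


class TestPreprocess:
    def _lib(self, positions, lib_id="a"):
        return JunctionLibrary(lib_id, [_rec(p) for p in positions], 0)

    def test_exclusion_interval_junctions_removed(self):
        libs = [self._lib([50_100, 1000]), self._lib([2000, 3000], "b")]
        out = preprocess_3c(libs, BAIT, ("chr1", 0, 100_000), seed=0)
        assert all(
            not (50_060 <= r.junction_pos < 50_200) for lib in out for r in lib.records
        )

    def test_region_restriction(self):
        libs = [self._lib([1000, 99_999_999]), self._lib([2000, 3000], "b")]
        out = preprocess_3c(libs, BAIT, ("chr1", 0, 100_000), seed=0)
        assert all(r.junction_pos < 100_000 for lib in out for r in lib.records)

    def test_all_libraries_normalized_to_minimum(self):
        rng = np.random.default_rng(1)
        libs = [
            self._lib(rng.integers(0, 40_000, n).tolist(), lib_id=f"l{n}")
            for n in (600, 550, 520)
        ]
        out = preprocess_3c(libs, BAIT, ("chr1", 0, 100_000), seed=0)
        assert [len(lib.records) for lib in out] == [520, 520, 520]

    def test_empty_retained_set_is_an_error(self):
        libs = [self._lib([500_000])]  # outside region
        with pytest.raises(ValueError, match="no junctions retained"):
            preprocess_3c(libs, BAIT, ("chr1", 0, 100_000), seed=0)


class TestRollingMedian:
    def test_constant_counts_give_constant_lambda(self):
        lam = rolling_median_lambda(np.full(500, 7), window=101)
        assert (lam == 7).all()

    def test_truncated_window_median(self):
        lam = rolling_median_lambda(np.array([1, 2, 100, 2, 1]), window=101)
        assert lam[2] == 2  # median of (1, 1, 2, 2, 100)

    def test_outlier_robustness(self):
        counts = np.array([1, 1, 1, 100, 1, 1, 1])
        lam = rolling_median_lambda(counts, window=101)
        assert lam[3] == 1

    def test_lower_middle_convention_on_even_windows(self):
        # at index 0 of (1, 2): truncated window = (1, 2), lower middle = 1
        lam = rolling_median_lambda(np.array([1, 2]), window=3)
        assert lam[0] == 1

    def test_lambda_always_at_least_one(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3, 1000) + 1
        assert (rolling_median_lambda(counts) >= 1).all()

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            rolling_median_lambda(np.array([]))


class TestPoissonTail:
    def test_zero_count_has_probability_one(self):
        assert poisson_upper_p(0, 5.0) == 1.0

    def test_known_tail_value(self):
        # P(X >= 5 | lam=1) = 1 - e^-1 * (1 + 1 + 1/2 + 1/6 + 1/24)
        expected = 1.0 - math.exp(-1) * (65.0 / 24.0)
        assert poisson_upper_p(5, 1.0) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 60), st.sampled_from([0.1, 1.0, 5.0, 20.0]))
    @settings(deadline=None, max_examples=60)
    def test_monotone_nonincreasing_in_k(self, k, lam):
        assert poisson_upper_p(k + 1, lam) <= poisson_upper_p(k, lam)

    def test_bad_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_upper_p(1, 0.0)


def _stats(raw_p, positions=None):
    raw_p = np.asarray(raw_p, dtype=float)
    if positions is None:
        positions = np.arange(raw_p.size) * 100 + 100
    return SiteStats(
        chrom="chr1",
        positions=np.asarray(positions, dtype=np.int64),
        counts=np.ones(raw_p.size, dtype=np.int64),
        lam=np.ones(raw_p.size),
        raw_p=raw_p,
    )


class TestCallPeaks:
    def test_no_significant_site_gives_no_peaks(self):
        assert call_peaks_single(_stats([0.5, 0.4, 0.3, 0.6]), alpha=0.05) == []

    def test_hand_traced_seven_site_walk(self):
        # summit at index 3 (adj_p = 7e-6); immediate neighbours (0.9) are
        # raw-P local maxima >= 0.05 -> region spans exactly sites 2..4
        stats_ = _stats([0.3, 0.2, 0.9, 1e-6, 0.9, 0.2, 0.3])
        peaks = call_peaks_single(stats_, alpha=0.05)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end) == (300, 501)
        assert p.summit_pos == 400
        assert p.summit_raw_p == 1e-6
        assert p.summit_adj_p == pytest.approx(7e-6)

    def test_walk_passes_non_local_max_stops(self):
        # index 2 (0.3) has raw_p >= 0.05 but is not a local max (0.9 next to
        # it): the walk continues to index 1
        stats_ = _stats([0.5, 0.9, 0.3, 1e-6, 0.3, 0.9, 0.5])
        peaks = call_peaks_single(stats_, alpha=0.05)
        assert (peaks[0].start, peaks[0].end) == (200, 601)

    def test_walk_reaching_array_end_stops_at_last_site(self):
        stats_ = _stats([0.01, 0.02, 1e-6, 0.02, 0.01])
        peaks = call_peaks_single(stats_, alpha=0.05)
        assert (peaks[0].start, peaks[0].end) == (100, 501)

    def test_overlapping_regions_merge_keeping_best_summit(self):
        raw = [0.9, 1e-6, 0.2, 1e-8, 0.9, 0.5, 0.5]
        peaks = call_peaks_single(_stats(raw), alpha=0.05)
        assert len(peaks) == 1
        assert peaks[0].summit_raw_p == 1e-8

    def test_regions_pairwise_disjoint_after_merge(self):
        rng = np.random.default_rng(8)
        raw = rng.uniform(0, 1, 300)
        raw[rng.choice(300, 12, replace=False)] = 1e-9
        peaks = call_peaks_single(_stats(raw), alpha=0.05)
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            call_peaks_single(_stats([0.5]), alpha=1.5)

    def test_bonferroni_uses_number_of_tested_sites(self):
        # raw_p 0.004 over 10 sites -> adj 0.04 < 0.05: summit; over 20 sites
        # -> adj 0.08: no summit
        raw10 = np.full(10, 0.9)
        raw10[5] = 0.004
        assert len(call_peaks_single(_stats(raw10), alpha=0.05)) == 1
        raw20 = np.full(20, 0.9)
        raw20[5] = 0.004
        assert call_peaks_single(_stats(raw20), alpha=0.05) == []


def _region(start, end, raw_p=1e-6, chrom="chr1"):
    return PeakRegion(chrom, start, end, (start + end) // 2, raw_p, raw_p * 10)


class TestRobustPeaks:
    def test_two_of_three_repeats_kept(self):
        per_repeat = [[_region(100, 200)], [_region(150, 260, 1e-8)], []]
        robust = robust_peaks(per_repeat)
        assert len(robust) == 1
        assert robust[0].support == 2
        assert robust[0].start == 100 and robust[0].end == 260
        assert robust[0].summit_raw_p == 1e-8  # best summit across repeats

    def test_two_of_four_repeats_dropped(self):
        per_repeat = [[_region(100, 200)], [_region(150, 260)], [], []]
        assert robust_peaks(per_repeat) == []

    def test_three_of_four_repeats_kept(self):
        per_repeat = [[_region(100, 200)], [_region(150, 260)], [_region(180, 300)], []]
        robust = robust_peaks(per_repeat)
        assert len(robust) == 1 and robust[0].support == 3

    def test_one_of_two_repeats_dropped(self):
        assert robust_peaks([[_region(100, 200)], []]) == []

    def test_same_repeat_counted_once(self):
        # two overlapping regions from one repeat give support 1, not 2
        per_repeat = [[_region(100, 200), _region(150, 260)], []]
        assert robust_peaks(per_repeat) == []

    def test_repeat_count_outside_2_to_5_is_an_error(self):
        with pytest.raises(ValueError):
            robust_peaks([[_region(0, 10)]])

    def test_support_never_exceeds_repeat_count(self):
        per_repeat = [[_region(100, 200)] for _ in range(3)]
        robust = robust_peaks(per_repeat)
        assert robust[0].support == 3


class TestSiteStatsFromCounts:
    def test_zero_count_sites_excluded_from_testing(self):
        stats_ = site_stats_from_counts("chr1", [100, 200, 300], [3, 0, 2])
        assert stats_.n_tested == 2
        assert stats_.positions.tolist() == [100, 300]

    def test_raw_p_computed_against_moving_median(self):
        counts = np.full(50, 5)
        counts[25] = 30
        stats_ = site_stats_from_counts("chr1", np.arange(50) * 100, counts)
        assert stats_.lam[25] == 5
        assert stats_.raw_p[25] < 1e-10
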