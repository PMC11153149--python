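"""Generator determinism, planted-truth closure, and the generative modes."""

import numpy as np
import pytest
from scipy import stats

from ragscan.annotate import annotate_peaks, pwm_scan, reliable_cbes
from ragscan.rss import classify_orientation, scan_unannotated_rss, split_on_off_target
from ragscan.synthetic import (
    SimConfig,
    make_synthetic_locus,
    simulate_3c_library,
    simulate_site_count_track,
    simulate_tracks,
    simulate_vdj_library,
)
from ragscan.types import PeakRegion


class TestLocus:
    def test_same_seed_gives_identical_sequence(self):
        cfg = SimConfig(locus_length=60_000)
        a = make_synthetic_locus(cfg, seed=3)
        b = make_synthetic_locus(cfg, seed=3)
        assert a.genome.sequences == b.genome.sequences

    def test_different_seed_gives_different_sequence(self):
        cfg = SimConfig(locus_length=60_000)
        a = make_synthetic_locus(cfg, seed=3)
        b = make_synthetic_locus(cfg, seed=4)
        assert a.genome.sequences != b.genome.sequences

    def test_restriction_map_positions_carry_catg(self, small_locus):
        locus, _ = small_locus
        seq = locus.genome.sequences[locus.config.chrom]
        positions = locus.rmap.positions(locus.config.chrom)
        assert len(positions) > 100
        assert all(seq[p : p + 4] == "CATG" for p in positions)

    def test_scanner_recovers_exactly_the_planted_rss_set(self, small_locus):
        locus, _ = small_locus
        found = scan_unannotated_rss(locus.genome, max_mismatch=4)
        got = {(s.chrom, s.cleavage_pos, s.orientation) for s in found}
        planted = {(s.chrom, s.rss_cleavage_pos, s.orientation) for s in locus.segments}
        assert got == planted
        assert all(s.mismatches == 0 for s in found)  # planted sites are ideal

    def test_too_short_locus_rejected(self):
        with pytest.raises(ValueError, match="50 kb"):
            make_synthetic_locus(SimConfig(locus_length=10_000), seed=0)

    def test_cryptic_cac_sites_carry_cac_in_orientation(self, small_locus):
        locus, _ = small_locus
        seq = locus.genome.sequences[locus.config.chrom]
        for c in locus.cac_catalog[:50]:
            if c.orientation == "+":
                assert seq[c.pos : c.pos + 3] == "CAC"
            else:
                assert seq[c.pos - 2 : c.pos + 1] == "GTG"


class TestVdjSimulation:
    def test_read_totals_conserved(self, small_locus):
        locus, cfg = small_locus
        lib = simulate_vdj_library(locus, cfg, seed=2)
        assert lib.total_reads == cfg.n_total_reads
        n_junctions = round(cfg.n_total_reads * cfg.junction_fraction)
        assert len(lib.records) == n_junctions

    def test_same_seed_reproduces_library(self, small_locus):
        locus, cfg = small_locus
        a = simulate_vdj_library(locus, cfg, seed=9)
        b = simulate_vdj_library(locus, cfg, seed=9)
        assert a.records == b.records

    def test_scanning_mode_junctions_deletional_and_bounded_by_impediment(self, small_locus):
        locus, cfg = small_locus
        lib = simulate_vdj_library(locus, cfg, seed=2)
        split = split_on_off_target(lib, locus.segments, [], tolerance=50)
        assert split.cryptic, "expected cryptic junctions at the configured rate"
        frac_del = np.mean(
            [
                classify_orientation(locus.bait.orientation, r.prey_orientation)
                == "deletional"
                for r in split.cryptic
            ]
        )
        impediment = int(0.30 * cfg.locus_length)
        assert frac_del >= 0.95
        assert min(r.junction_pos for r in split.cryptic) >= impediment

    def test_diffusion_mode_orientation_symmetric(self, small_locus):
        locus, _ = small_locus
        cfg = SimConfig(
            locus_length=120_000, n_total_reads=50_000, junction_fraction=0.4,
            cryptic_rate=0.5, mode="diffusion",
        )
        lib = simulate_vdj_library(locus, cfg, seed=3)
        split = split_on_off_target(lib, locus.segments, [], tolerance=50)
        n = len(split.cryptic)
        n_inv = sum(
            classify_orientation(locus.bait.orientation, r.prey_orientation) == "inversional"
            for r in split.cryptic
        )
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= n_inv <= hi

    def test_segment_strengths_recovered_by_multinomial_gof(self):
        cfg = SimConfig(
            locus_length=60_000, n_total_reads=125_000, junction_fraction=0.8,
            cryptic_rate=0.0, n_segments=2, segment_strengths=(3.0, 1.0),
        )
        locus = make_synthetic_locus(cfg, seed=5)
        lib = simulate_vdj_library(locus, cfg, seed=6)
        split = split_on_off_target(lib, locus.segments, [], tolerance=50)
        counts = {"V1": 0, "V2": 0}
        for sid in split.on_target_segment:
            counts[sid] += 1
        n = counts["V1"] + counts["V2"]
        assert n == 100_000
        res = stats.chisquare([counts["V1"], counts["V2"]], [0.75 * n, 0.25 * n])
        assert res.pvalue > 0.01

    def test_impediment_outside_locus_rejected(self, small_locus):
        locus, _ = small_locus
        bad = SimConfig(locus_length=120_000, scan_impediment_pos=500_000)
        with pytest.raises(ValueError, match="impediment"):
            simulate_vdj_library(locus, bad, seed=0)


class TestThreeCSimulation:
    def test_total_junctions_exact(self, small_locus):
        locus, cfg = small_locus
        lib = simulate_3c_library(locus.rmap, locus.bait, cfg, seed=1, n_junctions=20_000)
        assert len(lib.records) == 20_000

    def test_mean_counts_follow_decay_curve(self, small_locus):
        # equal-distance site pairs (one left, one right of the bait) should
        # have equal expected counts; compare near-vs-far mean ratio to the
        # power law over replicates
        locus, _ = small_locus
        cfg = SimConfig(locus_length=120_000, decay_exponent=1.0, self_ligation_weight=0.0)
        sites = locus.rmap.positions(locus.bait.chrom)
        d = np.abs(sites - locus.bait.cleavage_pos).astype(float)
        weights = (1 + d) ** -1.0
        near = int(np.argsort(d)[50])
        far = int(np.argsort(d)[600])
        expected_ratio = weights[near] / weights[far]
        tot_near = tot_far = 0
        for rep in range(60):
            lib = simulate_3c_library(locus.rmap, locus.bait, cfg, seed=100 + rep,
                                      n_junctions=30_000)
            pos = np.array([r.junction_pos for r in lib.records])
            tot_near += int((pos == sites[near]).sum())
            tot_far += int((pos == sites[far]).sum())
        assert tot_far > 0
        ratio = tot_near / tot_far
        assert ratio == pytest.approx(expected_ratio, rel=0.25)

    def test_anchor_enrichment_scales_expected_count(self, small_locus):
        locus, _ = small_locus
        base = SimConfig(locus_length=120_000, self_ligation_weight=0.0)
        enr = SimConfig(locus_length=120_000, self_ligation_weight=0.0, anchors=((300, 8.0),))
        sites = locus.rmap.positions(locus.bait.chrom)
        c_base = c_enr = 0
        for rep in range(40):
            for cfg, acc in ((base, "b"), (enr, "e")):
                lib = simulate_3c_library(locus.rmap, locus.bait, cfg, seed=500 + rep,
                                          n_junctions=30_000)
                pos = np.array([r.junction_pos for r in lib.records])
                k = int((pos == sites[300]).sum())
                if acc == "b":
                    c_base += k
                else:
                    c_enr += k
        assert c_base > 0
        assert c_enr / c_base == pytest.approx(8.0, rel=0.25)

    def test_anchor_index_out_of_range_rejected(self, small_locus):
        locus, _ = small_locus
        cfg = SimConfig(locus_length=120_000, anchors=((10**7, 8.0),))
        with pytest.raises(ValueError, match="out of range"):
            simulate_3c_library(locus.rmap, locus.bait, cfg, seed=0)

    def test_too_few_restriction_sites_rejected(self, small_locus):
        locus, cfg = small_locus
        from ragscan.genome import RestrictionMap

        tiny = RestrictionMap({locus.bait.chrom: [10, 20, 30]})
        with pytest.raises(ValueError, match="500"):
            simulate_3c_library(tiny, locus.bait, cfg, seed=0)


class TestSiteCountTrack:
    def test_deterministic_given_seed(self):
        a = simulate_site_count_track(1000, 20.0, [(5, 8.0)], seed=1)
        b = simulate_site_count_track(1000, 20.0, [(5, 8.0)], seed=1)
        assert np.array_equal(a[1], b[1])

    def test_anchor_counts_enriched(self):
        rng = np.random.default_rng(0)
        anchor_counts = []
        for s in range(50):
            _, counts = simulate_site_count_track(200, 20.0, [(100, 8.0)], seed=s)
            anchor_counts.append(counts[100])
        assert np.mean(anchor_counts) == pytest.approx(160.0, rel=0.1)


class TestTracks:
    def test_planted_features_produce_exact_labels(self, feature_locus):
        locus, cfg = feature_locus
        tracks = simulate_tracks(locus, seed=11)
        matrix = np.ones((4, len(cfg.cbe_consensus)))
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, b in enumerate(cfg.cbe_consensus):
            matrix[idx[b], i] = 100.0
        hits = pwm_scan(locus.genome, matrix, threshold=13.0)
        cbes = reliable_cbes(hits, tracks.chip_repeats)
        assert {h.start for h in cbes} == set(cfg.cbe_positions)

        def peak_at(p, name):
            return PeakRegion(cfg.chrom, p - 100, p + 100, p, 1e-9, 1e-7, name=name)

        peaks = [
            peak_at(cfg.cbe_positions[0], "cbe_peak"),
            peak_at(cfg.e2a_positions[0], "e2a_peak"),
            peak_at(cfg.transcription_positions[0], "txn_peak"),
            peak_at(90_000, "bare_peak"),
        ]
        feats = annotate_peaks(peaks, cbes, tracks.e2a, tracks.gro_repeats)
        by_name = {f.peak_name: f.labels for f in feats}
        assert by_name["cbe_peak"] == {"C"}
        assert by_name["e2a_peak"] == {"E"}
        assert by_name["txn_peak"] == {"T"}
        assert by_name["bare_peak"] == {"U"}

    def test_feature_outside_locus_rejected(self, feature_locus):
        locus, _ = feature_locus
        locus2 = type(locus)(
            genome=locus.genome, segments=locus.segments, cac_catalog=locus.cac_catalog,
            rmap=locus.rmap, bait=locus.bait, config=locus.config,
            cbe_positions=(10**9,),
        )
        with pytest.raises(ValueError, match="outside locus"):
            simulate_tracks(locus2, seed=0)
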