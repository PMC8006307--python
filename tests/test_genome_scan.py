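"""Window smoothing, thresholds, region calling, and consensus intersection."""

import numpy as np
import pandas as pd
import pytest

from coldmap.genome_scan import (
    CandidateRegion,
    ThresholdSet,
    call_regions,
    delta_null_band,
    empirical_thresholds,
    intersect_regions,
    make_windows,
    nearest_rank_quantile,
    smooth_track,
)


class TestWindows:
    def test_grid_starts(self):
        w = make_windows({"chr1": 100_000}, window_size=50_000, step=25_000)
        assert w["start"].tolist() == [1, 25_001, 50_001, 75_001]
        assert w["end"].tolist() == [50_000, 75_000, 100_000, 100_000]

    def test_step_equal_window_tiles(self):
        w = make_windows({"chr1": 100_000}, window_size=25_000, step=25_000)
        assert (w["start"].to_numpy()[1:] == w["end"].to_numpy()[:-1] + 1).all()

    def test_oversized_window_clipped(self):
        w = make_windows({"chr1": 10_000}, window_size=50_000, step=50_000)
        assert len(w) == 1
        assert w.loc[0, "end"] == 10_000

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 100}, window_size=10, step=20)


def stats_frame(positions, delta=0.5, g=10.0, ed=0.7, p=0.01, chrom="chr1"):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": positions,
            "delta": np.broadcast_to(delta, n).astype(float),
            "g": np.broadcast_to(g, n).astype(float),
            "ed": np.broadcast_to(ed, n).astype(float),
            "fisher_p": np.broadcast_to(p, n).astype(float),
            "t_depth": [100.0] * n,
            "s_depth": [100.0] * n,
        }
    )


class TestSmoothing:
    def test_single_snp_window_equals_raw(self):
        stats = stats_frame([500_000], delta=0.42, g=7.5, ed=0.6, p=0.001)
        windows = make_windows({"chr1": 1_000_000}, 1_000_000, 1_000_000)
        track = smooth_track(stats, windows, min_snps=1)
        assert track.loc[0, "delta"] == pytest.approx(0.42)
        assert track.loc[0, "g_prime"] == pytest.approx(7.5)
        assert track.loc[0, "ed"] == pytest.approx(0.6)
        assert track.loc[0, "fisher_neglog10p"] == pytest.approx(3.0)

    def test_constant_statistic_preserved(self):
        stats = stats_frame(np.arange(1, 1_000_000, 5_000))
        windows = make_windows({"chr1": 1_000_000}, 200_000, 100_000)
        track = smooth_track(stats, windows, min_snps=1)
        assert np.allclose(track["delta"].dropna(), 0.5)
        assert np.allclose(track["g_prime"].dropna(), 10.0)

    def test_tricube_weighted_mean_hand_computed(self):
        pos = np.array([100_000, 250_000, 500_000, 700_000, 950_000])
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stats = stats_frame(pos, g=1.0)
        stats["g"] = g
        windows = make_windows({"chr1": 1_000_000}, 1_000_000, 1_000_000)
        track = smooth_track(stats, windows, min_snps=1)
        center = (1 + 1_000_000) / 2.0
        h = 1_000_000 / 2.0
        w = (1 - (np.abs(pos - center) / h) ** 3) ** 3
        expected = (w * g).sum() / w.sum()
        assert track.loc[0, "g_prime"] == pytest.approx(expected, abs=1e-9)

    def test_sparse_windows_missing(self):
        stats = stats_frame([500_000])
        windows = make_windows({"chr1": 1_000_000}, 1_000_000, 1_000_000)
        track = smooth_track(stats, windows, min_snps=5)
        assert np.isnan(track.loc[0, "delta"])

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 200, replace=False))
        stats = stats_frame(pos, delta=0.1)
        stats["delta"] = rng.normal(0, 0.2, len(stats))
        windows = make_windows({"chr1": 2_000_000}, 500_000, 100_000)
        t1 = smooth_track(stats, windows, min_snps=1)
        t2 = smooth_track(
            stats.sample(frac=1.0, random_state=1).reset_index(drop=True),
            windows,
            min_snps=1,
        )
        assert np.allclose(t1["delta"], t2["delta"], equal_nan=True)


class TestThresholds:
    def test_nearest_rank_convention(self):
        vals = np.arange(1, 101, dtype=float)
        assert nearest_rank_quantile(vals, 0.95) == 95.0
        assert nearest_rank_quantile(vals, 0.99) == 99.0

    def test_degenerate_distribution(self):
        vals = np.full(200, 3.14)
        assert nearest_rank_quantile(vals, 0.95) == pytest.approx(3.14)

    def test_thresholds_increase_with_confidence(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), 2_000, replace=False))
        stats = stats_frame(pos)
        stats["g"] = rng.gamma(2.0, 2.0, len(stats))
        stats["delta"] = rng.normal(0, 0.1, len(stats))
        windows = make_windows({"chr1": 20_000_000}, 1_000_000, 100_000)
        track = smooth_track(stats, windows, min_snps=1)
        ts = empirical_thresholds(track)
        for m in ("delta", "g", "ed", "fisher"):
            assert ts.get(m, 0.99) >= ts.get(m, 0.95)

    def test_too_few_windows_rejected(self):
        stats = stats_frame([500_000])
        windows = make_windows({"chr1": 1_000_000}, 1_000_000, 1_000_000)
        track = smooth_track(stats, windows, min_snps=1)
        with pytest.raises(ValueError):
            empirical_thresholds(track)


class TestDeltaNullBand:
    def test_quantile_monotonic_in_confidence(self):
        b95 = delta_null_band(30, 50, n_sim=20_000, confidence=0.95, seed=1)
        b99 = delta_null_band(30, 50, n_sim=20_000, confidence=0.99, seed=1)
        assert b99 >= b95

    def test_consistency_limit(self):
        band = delta_null_band(5000, 100_000, n_sim=5_000, confidence=0.95, seed=1)
        assert band < 0.02

    def test_monte_carlo_self_consistency(self):
        a = delta_null_band(30, 50, n_sim=100_000, confidence=0.95, seed=1)
        b = delta_null_band(30, 50, n_sim=100_000, confidence=0.95, seed=2)
        assert abs(a - b) < 0.01

    def test_small_n_sim_warns(self):
        with pytest.warns(UserWarning):
            delta_null_band(30, 50, n_sim=500, confidence=0.95, seed=1)


def track_with_bump(n_windows=300, bump=slice(100, 120), value=5.0):
    track = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_windows) * 20_000 + 1,
            "end": np.arange(n_windows) * 20_000 + 1_000_000,
            "delta": 0.0,
            "g_prime": 1.0,
            "ed": 0.1,
            "fisher_neglog10p": 0.5,
            "t_depth": 100.0,
            "s_depth": 100.0,
            "n_snps": 50,
        }
    )
    track.loc[bump, "g_prime"] = value
    return track


def fixed_thresholds(value=2.0):
    return ThresholdSet(
        values={m: {0.95: value, 0.99: value} for m in ("delta", "g", "ed", "fisher")}
    )


class TestCallRegions:
    def test_no_windows_above_threshold(self):
        regions = call_regions(track_with_bump(value=1.5), "g", fixed_thresholds(), 0.95)
        assert regions == []

    def test_single_run_single_region(self):
        track = track_with_bump()  # windows 100..120 above threshold
        regions = call_regions(track, "g", fixed_thresholds(), 0.95)
        assert len(regions) == 1
        r = regions[0]
        assert r.start == track.loc[100, "start"]
        assert r.end == track.loc[120, "end"]
        assert r.peak == pytest.approx(5.0)

    def test_gap_of_one_window_bridged(self):
        track = track_with_bump()
        track.loc[110, "g_prime"] = 1.0  # one-window dropout
        regions = call_regions(track, "g", fixed_thresholds(), 0.95, gap_windows=1)
        assert len(regions) == 1

    def test_min_region_filter(self):
        track = track_with_bump(bump=slice(100, 101), value=5.0)
        regions = call_regions(
            track, "g", fixed_thresholds(), 0.95, min_region=2_000_000
        )
        assert regions == []


def region(method, start, end, chrom="chr9", peak=1.0):
    return CandidateRegion(method, chrom, start, end, peak, 0.99)


class TestConsensus:
    def test_reported_interval_arithmetic(self):
        by_method = {
            "delta": [region("delta", 11_160_001, 20_500_000, peak=0.76226)],
            "g": [region("g", 13_340_001, 18_740_000, peak=55.11879)],
            "ed": [region("ed", 13_380_001, 18_740_000, peak=1.182111)],
            "fisher": [region("fisher", 13_200_001, 18_740_000, peak=0.001811)],
        }
        consensus = intersect_regions(by_method)
        assert len(consensus) == 1
        c = consensus[0]
        assert (c.start, c.end) == (13_380_001, 18_740_000)

    def test_disjoint_intervals_empty(self):
        by_method = {
            "a": [region("a", 100, 200)],
            "b": [region("b", 300, 400)],
        }
        assert intersect_regions(by_method) == []

    def test_single_method_identity(self):
        by_method = {"a": [region("a", 100, 200)]}
        consensus = intersect_regions(by_method)
        assert (consensus[0].start, consensus[0].end) == (100, 200)

    def test_chromosome_without_full_support_dropped(self):
        by_method = {
            "a": [region("a", 100, 200), region("a", 100, 200, chrom="chr2")],
            "b": [region("b", 150, 250)],
        }
        consensus = intersect_regions(by_method)
        assert [c.chrom for c in consensus] == ["chr9"]

    def test_consensus_contained_in_supports(self, planted_result):
        for conf, regions in planted_result.consensus.items():
            for c in regions:
                for m in c.methods:
                    assert any(
                        r.chrom == c.chrom and r.start <= c.start and r.end >= c.end
                        for r in planted_result.regions[conf][m]
                    )
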