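"""Origin-calling chain: smoothing, normalization, the transition metric,
peak calling, annotation, spacing statistics and map comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from okmap import origins as om
from okmap import simulate
from okmap.core import StrandedTrack
from tests.conftest import make_track


def balanced_track(n_bins=600, depth=5.0, bin_size=100):
    v = np.full(n_bins, depth)
    return make_track(v.copy(), v.copy(), bin_size)


class TestSmoothTrack:
    def test_constant_track_unchanged(self):
        t = balanced_track()
        sm = om.smooth_track(t, 1500)
        np.testing.assert_allclose(sm.watson["chrT"], t.watson["chrT"])

    def test_single_spike_removed(self):
        w = np.zeros(100)
        w[50] = 100.0
        c = np.ones(100)  # keep bins unmasked
        sm = om.smooth_track(make_track(w, c), 1500)
        assert sm.watson["chrT"][50] == 0.0  # median of 14 zeros and one 100

    def test_matches_bruteforce_median_with_mask(self):
        rng = np.random.default_rng(7)
        n = 1000
        w = rng.poisson(6, n).astype(float)
        c = rng.poisson(6, n).astype(float)
        dead = rng.random(n) < 0.1
        w[dead] = 0.0
        c[dead] = 0.0
        track = make_track(w, c)
        sm = om.smooth_track(track, 1500)  # 15-bin window
        h = 7
        mask = track.mask("chrT")
        for i in rng.integers(0, n, 200):
            lo, hi = max(0, i - h), min(n, i + h + 1)
            vals = w[lo:hi][~mask[lo:hi]]
            expected = np.median(vals) if len(vals) else 0.0
            assert sm.watson["chrT"][i] == pytest.approx(expected)

    def test_window_below_bin_size_rejected(self):
        with pytest.raises(ValueError):
            om.smooth_track(balanced_track(), 50)


class TestNormalizeTrack:
    @pytest.mark.parametrize("w,c,expected", [(10, 0, 1.0), (5, 5, 0.5),
                                              (0, 10, 0.0)])
    def test_fractions(self, w, c, expected):
        t = make_track(np.array([float(w)]), np.array([float(c)]))
        n = om.normalize_track(t)
        assert n.frac_watson["chrT"][0] == pytest.approx(expected)
        assert n.frac_watson["chrT"][0] + n.frac_crick["chrT"][0] == pytest.approx(1.0)

    def test_zero_coverage_masked(self):
        t = make_track(np.array([0.0]), np.array([0.0]))
        n = om.normalize_track(t)
        assert np.isnan(n.frac_watson["chrT"][0])


class TestTransitionMetric:
    def test_perfect_transition_scores_one(self):
        n = 400
        w = np.r_[np.full(200, 10.0), np.zeros(200)]
        c = np.r_[np.zeros(200), np.full(200, 10.0)]
        m = om.origin_transition_metric(make_track(w, c), 12_000)["chrT"]
        assert m[200] == pytest.approx(1.0)

    def test_hand_computed_toy_track(self):
        # 10 bins, window = 2 bins per side
        w = np.array([4, 4, 2, 2, 1, 1, 0, 0, 0, 0], dtype=float)
        c = np.array([0, 0, 1, 1, 2, 2, 4, 4, 4, 4], dtype=float)
        track = make_track(w, c, bin_size=100)
        m = om.origin_transition_metric(track, 200)["chrT"]
        # b=2: left = bins 0,1 -> F_W = 8/8 = 1; right = bins 2,3 -> 4/6
        assert m[2] == pytest.approx(1.0 - 4.0 / 6.0)
        # b=5: left = bins 3,4 -> 3/6; right = bins 5,6 -> 1/7
        assert m[5] == pytest.approx(3.0 / 6.0 - 1.0 / 7.0)
        assert np.isnan(m[0]) and np.isnan(m[9])  # edge windows undefined

    def test_antisymmetric_under_strand_swap(self):
        rng = np.random.default_rng(1)
        w = rng.poisson(8, 500).astype(float)
        c = rng.poisson(8, 500).astype(float)
        m1 = om.origin_transition_metric(make_track(w, c), 2000)["chrT"]
        m2 = om.origin_transition_metric(make_track(c, w), 2000)["chrT"]
        np.testing.assert_allclose(m1, -m2, atol=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(2)
        w = rng.poisson(3, 500).astype(float)
        c = rng.poisson(3, 500).astype(float)
        m = om.origin_transition_metric(make_track(w, c), 3000)["chrT"]
        assert np.nanmax(np.abs(m)) <= 1.0

    def test_balanced_noise_near_zero_mean(self):
        rng = np.random.default_rng(3)
        w = rng.poisson(20, 2000).astype(float)
        c = rng.poisson(20, 2000).astype(float)
        m = om.origin_transition_metric(make_track(w, c), 12_000)["chrT"]
        assert abs(np.nanmean(m)) < 0.01

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            om.origin_transition_metric(balanced_track(), 100)


class TestCallOrigins:
    def test_all_masked_metric_no_calls(self):
        calls = om.call_origins({"chrT": np.full(100, np.nan)}, 100)
        assert len(calls) == 0

    def test_two_equal_maxima_keep_leftmost(self):
        m = np.full(300, np.nan)
        m[100:200] = 0.0
        m[120] = 0.5
        m[170] = 0.5  # 5 kb away at 100 bp bins -> within merge distance
        calls = om.call_origins({"chrT": m}, 100, threshold=0.1,
                                min_separation=12_000)
        assert len(calls) == 1
        assert calls["midpoint"].iloc[0] == 120 * 100 + 50

    def test_threshold_strict(self):
        m = np.full(300, np.nan)
        m[100:200] = 0.0
        m[150] = 0.1
        assert len(om.call_origins({"chrT": m}, 100, threshold=0.1)) == 0

    def test_distant_maxima_both_kept(self):
        m = np.zeros(600)
        m[100] = 0.5
        m[400] = 0.4  # 30 kb apart
        calls = om.call_origins({"chrT": m}, 100)
        assert calls["midpoint"].tolist() == [100 * 100 + 50, 400 * 100 + 50]


def _normalized_single_origin(e=1.0, n=1200, origin_bin=600, depth=10.0):
    """Noiseless profile of a sole origin with efficiency e in a balanced
    background: left of the origin f_W = 0.5 + e/2, right f_C = 0.5 + e/2."""
    w = np.full(n, depth)
    c = np.full(n, depth)
    w[:origin_bin] *= (1 + e)
    c[:origin_bin] *= (1 - e)
    c[origin_bin:] *= (1 + e)
    w[origin_bin:] *= (1 - e)
    return om.normalize_track(make_track(w, c))


class TestAnnotateEfficiency:
    def test_noiseless_certain_origin_full_efficiency(self):
        track = _normalized_single_origin(e=1.0)
        calls = pd.DataFrame({"chrom": ["chrT"], "midpoint": [60_000],
                              "score": [1.0], "flagged": [False]})
        out = om.annotate_efficiency(calls, track)
        assert out["efficiency"].iloc[0] == pytest.approx(1.0)

    def test_balanced_track_exactly_half(self):
        track = om.normalize_track(balanced_track(1000))
        calls = pd.DataFrame({"chrom": ["chrT"] * 3,
                              "midpoint": [30_000, 50_000, 70_000],
                              "score": [0.1] * 3, "flagged": [False] * 3})
        out = om.annotate_efficiency(calls, track)
        assert (out["efficiency"] == 0.5).all()

    def test_rfd_step_recovers_noiseless_efficiency(self):
        for e in (0.2, 0.5, 0.8):
            track = _normalized_single_origin(e=e)
            calls = pd.DataFrame({"chrom": ["chrT"], "midpoint": [60_000],
                                  "score": [e], "flagged": [False]})
            # midpoint bin is shared by both windows: tolerance of one part
            # in the 201-bin window
            out = om.annotate_efficiency(calls, track, mode="rfd_step")
            assert out["efficiency"].iloc[0] == pytest.approx(e, abs=0.01)

    def test_origin_outside_bounds_rejected(self):
        track = om.normalize_track(balanced_track(100))
        calls = pd.DataFrame({"chrom": ["chrT"], "midpoint": [10_000_000],
                              "score": [1.0], "flagged": [False]})
        with pytest.raises(ValueError):
            om.annotate_efficiency(calls, track)

    def test_unnormalized_track_rejected(self):
        calls = pd.DataFrame({"chrom": ["chrT"], "midpoint": [1000],
                              "score": [1.0], "flagged": [False]})
        with pytest.raises(ValueError, match="normalize"):
            om.annotate_efficiency(calls, balanced_track(100))


class TestTransitionZone:
    def test_symmetric_profile_symmetric_maxima(self):
        track = _normalized_single_origin(e=0.8)
        calls = pd.DataFrame({"chrom": ["chrT"], "midpoint": [60_000],
                              "score": [0.8], "flagged": [False]})
        out = om.annotate_transition_zone(calls, track)
        mid = 60_000
        w, c = out["watson_max_pos"].iloc[0], out["crick_max_pos"].iloc[0]
        assert w <= mid <= c
        assert out["transition_zone"].iloc[0] >= 0

    def test_noiseless_sharp_origin_zero_width_zone(self):
        """A point-source origin with no sampling noise has its Watson and
        Crick maxima flush against the midpoint (innermost tie-break), so the
        transition zone collapses to zero."""
        track = _normalized_single_origin(e=1.0)
        calls = pd.DataFrame({"chrom": ["chrT"], "midpoint": [60_000],
                              "score": [1.0], "flagged": [False]})
        out = om.annotate_transition_zone(calls, track)
        assert out["transition_zone"].iloc[0] <= 2 * track.bin_size


class TestSpacingStats:
    def test_regular_spacing(self):
        origins = pd.DataFrame({"chrom": ["c"] * 3,
                                "midpoint": [0, 40_000, 80_000]})
        st = om.spacing_stats(origins)
        assert st["median_spacing"] == 40_000
        assert st["fraction_within_100kb"] == 1.0

    def test_single_origin_empty_statistics(self):
        st = om.spacing_stats(pd.DataFrame({"chrom": ["c"], "midpoint": [5]}))
        assert np.isnan(st["median_spacing"])
        assert len(st["spacings"]) == 0

    def test_matches_bruteforce_median(self):
        rng = np.random.default_rng(5)
        origins = pd.DataFrame({
            "chrom": rng.choice(["a", "b"], 1000),
            "midpoint": rng.integers(0, 10_000_000, 1000),
        })
        st = om.spacing_stats(origins)
        brute = []
        for c in ("a", "b"):
            mids = np.sort(origins.loc[origins["chrom"] == c, "midpoint"])
            brute.extend(np.diff(mids).tolist())
        assert st["median_spacing"] == np.median(brute)


class TestCompareOriginMaps:
    @pytest.fixture
    def map_a(self):
        rng = np.random.default_rng(8)
        return pd.DataFrame({
            "chrom": "chrI",
            "midpoint": np.arange(20) * 40_000 + 20_000,
            "efficiency": rng.uniform(0.1, 0.9, 20),
        })

    def test_self_comparison_perfect(self, map_a):
        cmp = om.compare_origin_maps(map_a, map_a)
        assert cmp["spearman_r"] == pytest.approx(1.0)
        assert cmp["percent_overlap"] == 100.0

    def test_rank_reversal_gives_minus_one(self, map_a):
        b = map_a.copy()
        order = np.argsort(map_a["efficiency"].to_numpy())
        rev = map_a["efficiency"].to_numpy().copy()
        rev[order] = rev[order[::-1]]
        b["efficiency"] = rev
        cmp = om.compare_origin_maps(map_a, b)
        assert cmp["spearman_r"] == pytest.approx(-1.0)

    def test_disjoint_maps_zero_overlap(self, map_a):
        b = map_a.copy()
        b["midpoint"] = b["midpoint"] + 10_000
        cmp = om.compare_origin_maps(map_a, b)
        assert cmp["percent_overlap"] == 0.0

    def test_replicate_runs_agree(self, default_run):
        """Two independent fragment populations from the same replication
        program yield concordant origin maps."""
        from okmap import io as io_mod
        from okmap.config import RunConfig
        from okmap.pipeline import call_origins_from_track
        model = default_run["model"]
        frags = simulate.simulate_fragments(model, 1000, 500, seed=99)
        track = io_mod.bin_fragments(frags, model.chrom_sizes, 100)
        calls2, _ = call_origins_from_track(track, RunConfig())
        cmp = om.compare_origin_maps(default_run["calls"], calls2)
        assert cmp["percent_overlap"] >= 90.0
        assert cmp["spearman_r"] >= 0.5  # absolute-fraction efficiencies saturate


class TestStrandHeatmap:
    def test_rows_centered_and_unit_norm(self, default_run):
        hm = om.origin_strand_heatmap(default_run["calls"],
                                      default_run["normalized"])
        for mat in (hm["watson"], hm["crick"]):
            assert mat.shape[0] > 0
            nonzero = np.abs(mat).sum(axis=1) > 0
            np.testing.assert_allclose(mat.mean(axis=1), 0.0, atol=1e-9)
            np.testing.assert_allclose((mat[nonzero] ** 2).sum(axis=1), 1.0,
                                       atol=1e-9)

    def test_rows_ordered_by_transition_zone(self, default_run):
        hm = om.origin_strand_heatmap(default_run["calls"],
                                      default_run["normalized"])
        tz = hm["transition_zone"]
        assert np.all(np.diff(tz) >= 0)

    def test_constant_row_becomes_zero_vector(self):
        track = om.normalize_track(balanced_track(600))
        calls = pd.DataFrame({"chrom": ["chrT"], "midpoint": [30_000],
                              "score": [0.1], "efficiency": [0.5],
                              "transition_zone": [0.0],
                              "watson_max_pos": [30_000.0],
                              "crick_max_pos": [30_000.0], "flagged": [False]})
        hm = om.origin_strand_heatmap(calls, track, flank=10_000)
        assert np.all(hm["watson"] == 0.0)
        assert hm["degenerate_rows"] == [0]


class TestReplicationTime:
    def test_embryonic_worked_example(self):
        assert om.replication_time(75, 2.5) == 15.0

    @pytest.mark.parametrize("spacing,speed,expected",
                             [(0, 2.5, 0.0), (40, 2.5, 8.0), (100, 2.0, 25.0)])
    def test_closed_form(self, spacing, speed, expected):
        assert om.replication_time(spacing, speed) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            om.replication_time(75, 0)
        with pytest.raises(ValueError):
            om.replication_time(-1, 2.5)
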