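"""Depth ratios, segmentation, interval spans, MAE distance and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gv1scan import synthetic
from gv1scan.cnv import (
    DepthProfile,
    DistanceMatrix,
    RatioProfile,
    cluster_strains,
    depth_ratio,
    interval_span,
    mae_distance,
    mae_matrix,
    segment_ratio,
)
from gv1scan.intervals import parse_mb_interval


def _flat_profile(name, counts, window=10_000, lib=None):
    n = len(counts)
    starts = np.arange(0, n * window, window)
    return DepthProfile(name, "13", starts, starts + window,
                        np.asarray(counts, float), library_size=lib)


def _ratio(name, ratios, window=10_000):
    n = len(ratios)
    starts = np.arange(0, n * window, window)
    return RatioProfile(name, "13", starts, starts + window, np.asarray(ratios, float))


class TestDepthRatio:
    def test_identity(self, flat_profile_pair):
        a, b = flat_profile_pair
        rp = depth_ratio(a, b)
        np.testing.assert_allclose(rp.ratios, 1.0)

    def test_deleted_segment_near_zero(self):
        counts = [100.0] * 10
        strain = _flat_profile("s", [0.0] * 5 + [100.0] * 5, lib=1000.0)
        ref = _flat_profile("r", counts, lib=1000.0)
        rp = depth_ratio(strain, ref, pseudocount=0.5)
        assert np.all(rp.ratios[:5] < 0.01)

    def test_cn4_simulation_recovers_ratio_two(self):
        # duplicated interval: windowed ratio expectation CN/2 = 2.  Depth is
        # high enough that the ratio-of-counts Jensen bias (~CN/depth) is
        # well below the Monte-Carlo error of the window average.
        spec_dup = synthetic.StrainSpec(
            "dup", "x", ((0, 100_000_000, 4),), mean_depth=10_000.0
        )
        spec_ref = synthetic.StrainSpec("ref", "x", (), mean_depth=10_000.0)
        cfg = synthetic.SimConfig(("13", 0, 100_000_000), window_bp=10_000, seed=13)
        dup, ref = synthetic.gen_depth_profiles([spec_dup, spec_ref], cfg)
        rp = depth_ratio(dup, ref)
        n = rp.n_windows
        assert n == 10_000
        se = rp.ratios.std(ddof=1) / np.sqrt(n)
        assert abs(rp.ratios.mean() - 2.0) <= 3 * se

    def test_grid_mismatch_names_first_window(self):
        a = _flat_profile("a", [1.0] * 5)
        starts = np.arange(0, 50_000, 10_000) + 10_000
        b = DepthProfile("b", "13", starts, starts + 10_000, np.ones(5))
        with pytest.raises(ValueError, match="index 0"):
            depth_ratio(a, b)


class TestSegmentRatio:
    def test_flat_profile_no_calls(self):
        assert segment_ratio(_ratio("s", [1.0] * 50)) == []

    def test_deletion_block_recovered_with_span(self):
        # an 81-window homozygous deletion at 10 kb windows: one CN0 call
        # spanning ~810 kb with boundaries within one window of truth
        ratios = [1.0] * 100 + [0.0] * 81 + [1.0] * 100
        calls = segment_ratio(_ratio("s", ratios))
        assert len(calls) == 1
        c = calls[0]
        assert c.state == "0"
        assert abs(c.start_bp - 100 * 10_000) <= 10_000
        assert abs(c.end_bp - 181 * 10_000) <= 10_000
        assert c.span_kb == pytest.approx(810.0, abs=10.0)

    def test_abutting_states_share_boundary(self):
        ratios = [1.0] * 50 + [0.5] * 30 + [0.0] * 30 + [1.0] * 50
        calls = segment_ratio(_ratio("s", ratios))
        assert [c.state for c in calls] == ["1", "0"]
        assert abs(calls[0].end_bp - calls[1].start_bp) <= 10_000

    def test_boundary_error_bounded_on_noise_free_input(self):
        # noise-free: boundary error at most ceil(smooth/2) windows
        for smooth in (3, 5, 7):
            ratios = [1.0] * 40 + [0.0] * 20 + [1.0] * 40
            calls = segment_ratio(_ratio("s", ratios), smooth_windows=smooth)
            assert len(calls) == 1
            tol = -(-smooth // 2) * 10_000
            assert abs(calls[0].start_bp - 400_000) <= tol
            assert abs(calls[0].end_bp - 600_000) <= tol

    def test_single_window_excursions_suppressed(self):
        ratios = [1.0] * 20 + [0.0] + [1.0] * 20
        assert segment_ratio(_ratio("s", ratios)) == []

    def test_poisson_noise_deletion_recovery(self):
        spec = synthetic.StrainSpec(
            "del", "C57", ((*synthetic.DELETION_810KB, 0),), 100.0
        )
        ref = synthetic.StrainSpec("ref", "C57", (), 100.0)
        cfg = synthetic.SimConfig(synthetic.PANEL_REGION, window_bp=10_000, seed=17)
        p_del, p_ref = synthetic.gen_depth_profiles([spec, ref], cfg)
        calls = segment_ratio(depth_ratio(p_del, p_ref))
        assert len(calls) == 1
        c = calls[0]
        assert c.state == "0"
        assert abs(c.start_bp - synthetic.DELETION_810KB[0]) <= 10_000
        assert abs(c.end_bp - synthetic.DELETION_810KB[1]) <= 10_000

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError):
            segment_ratio(_ratio("s", [1.0, 1.0]), smooth_windows=5)


class TestIntervalSpan:
    @pytest.mark.parametrize(
        "text,unit,expected",
        [
            ("13:65.79–66.60 Mb", "kb", 810.0),
            ("13:65.47–66.96 Mb", "Mb", 1.49),
            ("13:65.45–66.60 Mb", "Mb", 1.15),
        ],
    )
    def test_printed_cnv_spans(self, text, unit, expected):
        iv = parse_mb_interval(text)
        assert interval_span(iv.start_bp, iv.end_bp, unit) == pytest.approx(expected)

    def test_inverted_raises(self):
        with pytest.raises(ValueError):
            interval_span(10, 10)


class TestMaeDistance:
    def test_identity_and_offset(self):
        a = _ratio("a", [1.0, 1.2, 0.8, 1.0])
        b = _ratio("b", [1.3, 1.5, 1.1, 1.3])
        assert mae_distance(a, a) == 0.0
        assert mae_distance(a, b) == pytest.approx(0.3)

    def test_matches_naive_median_oracle(self, rng):
        x = rng.random(1000)
        y = rng.random(1000)
        a, b = _ratio("a", x), _ratio("b", y)
        diffs = sorted(abs(u - v) for u, v in zip(x, y))
        naive = (diffs[499] + diffs[500]) / 2  # sort-and-middle
        assert mae_distance(a, b) == naive

    def test_mean_variant(self):
        a = _ratio("a", [0.0, 0.0, 0.0, 1.0])
        b = _ratio("b", [0.0, 0.0, 0.0, 0.0])
        assert mae_distance(a, b, stat="median") == 0.0
        assert mae_distance(a, b, stat="mean") == pytest.approx(0.25)

    @given(st.lists(st.floats(0, 5), min_size=3, max_size=30),
           st.lists(st.floats(0, 5), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_nonnegativity(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = _ratio("a", xs[:n]), _ratio("b", ys[:n])
        assert mae_distance(a, b) == mae_distance(b, a) >= 0.0


class TestClusterStrains:
    def test_identical_strains_merge_first_at_zero(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]),
        )
        res = cluster_strains(d)
        assert res.linkage_matrix[0, 2] == 0.0  # first merge height
        assert frozenset({"a", "b"}) in res.groups()

    def test_two_lineage_recovery(self, small_panel_profiles):
        ref = small_panel_profiles[0]
        ratios = [depth_ratio(p, ref) for p in small_panel_profiles]
        res = cluster_strains(mae_matrix(ratios), n_groups=2)
        groups = sorted(sorted(g) for g in res.groups())
        assert groups == [
            ["129", "AJ", "BALBc", "CBA", "ZALENDE"],
            ["B10", "B6J", "B6N", "C57BR", "C57L"],
        ]

    def test_input_order_invariance(self, small_panel_profiles):
        ref = small_panel_profiles[0]
        ratios = [depth_ratio(p, ref) for p in small_panel_profiles]
        base = cluster_strains(mae_matrix(ratios)).groups()
        perm = [ratios[i] for i in [3, 0, 7, 1, 9, 5, 2, 8, 4, 6]]
        shuffled = cluster_strains(mae_matrix(perm)).groups()
        assert set(base) == set(shuffled)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestGenDepthProfiles:
    def test_noise_free_expectations(self):
        spec0 = synthetic.StrainSpec("del", "x", ((0, 50_000, 0),), 100.0)
        ref = synthetic.StrainSpec("ref", "x", (), 100.0)
        cfg = synthetic.SimConfig(("13", 0, 100_000), window_bp=10_000,
                                  noise_model="none", seed=0)
        p_del, p_ref = synthetic.gen_depth_profiles([spec0, ref], cfg)
        np.testing.assert_allclose(p_ref.counts, 100.0)
        np.testing.assert_allclose(p_del.counts[:5], 0.0)
        np.testing.assert_allclose(p_del.counts[5:], 100.0)

    def test_partial_window_dropped(self):
        cfg = synthetic.SimConfig(("13", 0, 25_000), window_bp=10_000, seed=0)
        starts, ends = cfg.window_grid()
        assert len(starts) == 2 and ends[-1] == 20_000

    def test_seed_determinism(self):
        specs = synthetic.default_strain_panel()
        cfg = synthetic.SimConfig(synthetic.PANEL_REGION, seed=21)
        a = synthetic.gen_depth_profiles(specs, cfg)
        b = synthetic.gen_depth_profiles(specs, cfg)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.counts, pb.counts)

    def test_negative_binomial_overdispersion(self):
        spec = synthetic.StrainSpec("s", "x", (), 100.0)
        ref = synthetic.StrainSpec("r", "x", (), 100.0)
        cfg = synthetic.SimConfig(("13", 0, 50_000_000), window_bp=10_000,
                                  noise_model="negative_binomial",
                                  dispersion=0.1, seed=31)
        p, _ = synthetic.gen_depth_profiles([spec, ref], cfg)
        # variance mu + dispersion mu^2 = 100 + 0.1*10000 = 1100 >> Poisson 100
        assert p.counts.var() > 500

    def test_invalid_configs(self):
        ref = synthetic.StrainSpec("r", "x", (), 100.0)
        with pytest.raises(ValueError):
            synthetic.SimConfig(("13", 0, 0), window_bp=10)
        with pytest.raises(ValueError):
            synthetic.SimConfig(("13", 0, 100), window_bp=200)
        with pytest.raises(ValueError):
            synthetic.gen_depth_profiles([ref], synthetic.SimConfig(("13", 0, 1000), window_bp=100))
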