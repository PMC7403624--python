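"""QC and normalisation: quantile normalisation, CV filters, growth rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import segvar as sv
import segvar.preprocess as pp


class TestQuantileNormalize:
    def test_hand_computed_three_by_two(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        out = pp.quantile_normalize(X)
        expect = np.array([5.5, 11.0, 16.5])
        assert np.allclose(out[:, 0], expect)
        assert np.allclose(out[:, 1], expect)

    def test_rank_identical_columns_become_identical(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        X = np.column_stack([a, np.exp(a)])  # same ranks, different scale
        out = pp.quantile_normalize(X)
        assert np.allclose(out[:, 0], out[:, 1])

    def test_common_multiset_across_complete_columns(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5)) * [1, 2, 3, 4, 5]
        out = pp.quantile_normalize(X)
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_idempotent_on_complete_data(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2.0, size=(25, 4))
        once = pp.quantile_normalize(X)
        twice = pp.quantile_normalize(once)
        assert np.allclose(once, twice)

    def test_all_missing_column_flagged_and_others_normalized(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        X = np.column_stack([X, [4.0, 5.0, 6.0]])
        with pytest.warns(UserWarning, match="all-missing"):
            out = pp.quantile_normalize(X)
        assert np.isnan(out[:, 1]).all()
        assert np.isfinite(out[:, [0, 2]]).all()

    def test_ties_get_mean_reference_value(self):
        X = np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        out = pp.quantile_normalize(X)
        # tied first-column values share the mean of the two lowest refs
        assert out[0, 0] == out[1, 0]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_ranks_preserved_within_columns(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        out = pp.quantile_normalize(X)
        for j in range(3):
            assert np.array_equal(np.argsort(out[:, j]), np.argsort(X[:, j]))


def _controls_with_cv(cv1, cv2, n_traits=1, mean=10.0):
    """Two-replicate control blocks with exact per-control CVs."""
    s1 = cv1 * mean / np.sqrt(2.0)
    s2 = cv2 * mean / np.sqrt(2.0)
    c1 = np.tile([[mean - s1], [mean + s1]], (1, n_traits))
    c2 = np.tile([[mean - s2], [mean + s2]], (1, n_traits))
    return c1, c2


class TestTraitConsistency:
    def test_identical_cvs_included_with_zero_distance(self):
        c1, c2 = _controls_with_cv(0.1, 0.1)
        tab = pp.assess_trait_consistency(c1, c2)
        assert tab["cv_distance"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert bool(tab["included"].iloc[0])
        assert tab["one_minus_cv"].iloc[0] == pytest.approx(0.9)

    def test_inconsistent_cvs_excluded_by_distance_index(self):
        # |0.3-0.1|/(0.3+0.1) = 0.5 > 0.2
        c1, c2 = _controls_with_cv(0.3, 0.1)
        tab = pp.assess_trait_consistency(c1, c2)
        assert tab["cv_distance"].iloc[0] == pytest.approx(0.5)
        assert tab["exclusion_reason"].iloc[0] == "inconsistent"

    def test_high_cv_excluded_before_distance(self):
        c1, c2 = _controls_with_cv(0.45, 0.45)
        tab = pp.assess_trait_consistency(c1, c2)
        assert tab["exclusion_reason"].iloc[0] == "high_cv"

    def test_zero_mean_trait_flagged_undefined(self):
        c1 = np.array([[-1.0], [1.0]])
        c2 = np.array([[9.0], [11.0]])
        tab = pp.assess_trait_consistency(c1, c2)
        assert tab["exclusion_reason"].iloc[0] == "undefined_cv"
        assert not bool(tab["included"].iloc[0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.01, 0.39), st.floats(0.01, 0.39))
    def test_distance_index_bounded_and_symmetric(self, cv1, cv2):
        c1, c2 = _controls_with_cv(cv1, cv2)
        d12 = pp.assess_trait_consistency(c1, c2)["cv_distance"].iloc[0]
        d21 = pp.assess_trait_consistency(c2, c1)["cv_distance"].iloc[0]
        assert 0.0 <= d12 <= 1.0
        assert d12 == pytest.approx(d21, rel=1e-9)


def _panel(counts, value=1.0):
    counts = np.asarray(counts)
    n, r = counts.shape
    values = np.full((n, 2, r), value)
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    names = np.array(["C1_A", "D2_C"], dtype=object)
    return sv.TraitPanel(ids, names, values, counts)


class TestCellCountFilter:
    def test_both_replicates_below_threshold_removes_segregant(self):
        panel = _panel([[79, 79], [100, 100]])
        out, rep = pp.filter_low_cell_count(panel, 80)
        assert list(out.segregant_ids) == ["s1"]
        assert not bool(rep["retained"].iloc[0])

    def test_one_passing_replicate_keeps_segregant(self):
        panel = _panel([[79, 120]])
        out, _ = pp.filter_low_cell_count(panel, 80)
        assert list(out.segregant_ids) == ["s0"]
        assert np.isnan(out.values[0, :, 0]).all()      # failing rep masked
        assert np.isfinite(out.values[0, :, 1]).all()

    def test_boundary_is_strict(self):
        panel = _panel([[80, 80]])
        out, _ = pp.filter_low_cell_count(panel, 80)
        assert np.isfinite(out.values).all()

    def test_zero_threshold_is_vacuous(self):
        panel = _panel([[5, 5], [1, 200]])
        out, rep = pp.filter_low_cell_count(panel, 0)
        assert rep["retained"].all()
        assert np.isfinite(out.values).all()


class TestAggregateReplicates:
    def test_mean_single_and_missing_replicates(self):
        values = np.array([[[2.0, 4.0]], [[7.0, np.nan]], [[np.nan, 5.0]]])
        panel = sv.TraitPanel(np.array(["a", "b", "c"], dtype=object),
                              np.array(["C1_A"], dtype=object), values,
                              np.full((3, 2), 100))
        means = pp.aggregate_replicates(panel)
        assert list(means["C1_A"]) == [3.0, 7.0, 5.0]


class TestGrowthRate:
    def test_linear_curve_constant_slope(self):
        times = np.arange(0.0, 25.0)
        od = (0.1 + 0.05 * times)[None, :]
        wells = pd.DataFrame({"plate": [1], "row": [0], "column": [0],
                              "segregant": ["s0"], "replicate": [1]})
        curves = sv.GrowthCurveSet(wells, times, od)
        tab = pp.extract_growth_rate(curves, correct_bias=False)
        assert tab["vmax_raw"].iloc[0] == pytest.approx(0.05, abs=1e-12)

    def test_planted_quadratic_bias_recovered(self):
        # identical segregants + smooth planted surface, zero noise:
        # corrected values constant across positions up to fit tolerance
        def quad(r, c, cfg):
            return 1.0 + 0.1 * ((r - 3.5) / 3.5) ** 2 - 0.08 * (c - 5.5) / 5.5
        cfg = sv.GrowthBiasConfig(noise_sd=0.0)
        curves = sv.simulate_growth_curves(np.full((96, 1), 0.1), cfg, 1,
                                           bias_surface=quad)
        tab = pp.extract_growth_rate(curves)
        assert tab["vmax_corrected"].std() < 1e-3

    def test_constant_bias_cancels_in_corrected_values(self):
        cfg = sv.GrowthBiasConfig(amplitude=0.0, noise_sd=0.0)
        rates = np.linspace(0.04, 0.08, 96).reshape(-1, 1)
        flat = lambda r, c, cfg: np.ones(len(r))          # noqa: E731
        double = lambda r, c, cfg: 2.0 * np.ones(len(r))  # noqa: E731
        t1 = pp.extract_growth_rate(
            sv.simulate_growth_curves(rates, cfg, 1, bias_surface=flat))
        t2 = pp.extract_growth_rate(
            sv.simulate_growth_curves(rates, cfg, 1, bias_surface=double))
        assert np.allclose(t2["vmax_raw"], 2 * t1["vmax_raw"], rtol=0.01)
        assert np.allclose(t2["vmax_corrected"], t1["vmax_corrected"],
                           rtol=0.01)

    def test_growth_rate_is_mean_of_corrected_replicates(self):
        tab = pd.DataFrame({"segregant": ["a", "a", "b"],
                            "vmax_corrected": [1.0, 3.0, 5.0]})
        out = pp.growth_rate_per_segregant(tab)
        assert out["a"] == 2.0 and out["b"] == 5.0

    def test_artifact_wells_reported_not_dropped(self):
        times = np.arange(0.0, 25.0)
        od = np.tile(0.1 + 0.02 * times, (2, 1))
        od[1, 12] += 0.5  # spike then crash
        wells = pd.DataFrame({"plate": [1, 1], "row": [0, 0],
                              "column": [0, 1], "segregant": ["a", "b"],
                              "replicate": [1, 1]})
        curves = sv.GrowthCurveSet(wells, times, od)
        with pytest.warns(UserWarning, match="non-monotone"):
            tab = pp.extract_growth_rate(curves, correct_bias=False)
        assert list(tab["artifact"]) == [False, True]
        assert len(tab) == 2


def test_filter_order_does_not_change_retained_ranks(adaptive_panel):
    """Cell-count filtering before vs after normalisation is rank-stable."""
    _, panel, _, _ = adaptive_panel
    panel = panel.copy()
    panel.cell_counts[:10, :] = 10  # force some removals
    a, _ = pp.filter_low_cell_count(panel, 80)
    na = pp.normalize_panel(a)
    nb_full = pp.normalize_panel(panel)
    keep = np.isin(panel.segregant_ids, a.segregant_ids)
    for t in range(5):
        for r in range(panel.n_replicates):
            va = na.values[:, t, r]
            vb = nb_full.values[keep, t, r]
            assert np.array_equal(np.argsort(va), np.argsort(vb))
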