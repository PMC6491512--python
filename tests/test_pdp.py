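"""Partial dependence, classification, thresholds, segmented correlation."""

import numpy as np
import pandas as pd
import pytest

import cogsense as cs
from cogsense.forest import ForestSpec
from cogsense.pdp import PDPCurve, pdp_grid

SMALL = ForestSpec(ntree=40, seed=0)


def naive_pdp_oracle(forest, table, variable):
    """Direct substitution-and-average, one grid value at a time."""
    grid = pdp_grid(table[variable].to_numpy(), 256)
    X = table[forest.predictors].to_numpy(dtype=float).copy()
    col = forest.predictors.index(variable)
    preds = []
    for v in grid:
        X[:, col] = v
        preds.append(float(np.mean(forest.model.predict(X))))
    return grid, np.array(preds)


def _tent(peak=420.0, lo=0.0, hi=840.0, n=85):
    grid = np.linspace(lo, hi, n)
    return PDPCurve("v", grid, -np.abs(grid - peak))


class TestPartialDependence:
    def test_unused_variable_gives_flat_curve(self, rng):
        # a constant column is never chosen for a split, so its PDP is flat
        t = pd.DataFrame({"x": rng.normal(size=80), "c": 1.0})
        t["y"] = 2 * t["x"] + rng.normal(scale=0.1, size=80)
        f = cs.fit_forest(t, ["x", "c"], "y", SMALL)
        curve = cs.partial_dependence(f, t, "c")
        assert np.ptp(curve.marginal_predictions) == 0

    def test_stump_gives_step_curve(self):
        # single depth-1 tree splitting on x: the PDP must be a two-level
        # step; verify against brute force over the stump's rule
        rng = np.random.default_rng(0)
        x = np.r_[rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)]
        t = pd.DataFrame({"x": x, "y": np.r_[np.zeros(50), np.ones(50)]})
        from sklearn.ensemble import RandomForestRegressor

        stump = RandomForestRegressor(
            n_estimators=1, max_depth=1, bootstrap=False, random_state=0
        ).fit(t[["x"]].to_numpy(), t["y"].to_numpy())
        forest = cs.FittedForest(stump, ["x"], "y")
        curve = cs.partial_dependence(forest, t, "x")
        split = stump.estimators_[0].tree_.threshold[0]
        expected = np.where(curve.grid <= split, 0.0, 1.0)
        assert np.array_equal(curve.marginal_predictions, expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_naive_substitution_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 3
        t = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(p)})
        t["y"] = t["x0"] ** 2 + t["x1"] + rng.normal(scale=0.3, size=n)
        f = cs.fit_forest(t, [f"x{i}" for i in range(p)], "y", ForestSpec(ntree=30, seed=seed))
        curve = cs.partial_dependence(f, t, "x0")
        grid, preds = naive_pdp_oracle(f, t, "x0")
        assert np.array_equal(curve.grid, grid)
        assert np.array_equal(curve.marginal_predictions, preds)

    def test_unknown_variable_rejected(self, rng):
        t = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)})
        f = cs.fit_forest(t, ["x"], "y", SMALL)
        with pytest.raises(ValueError, match="not a model predictor"):
            cs.partial_dependence(f, t, "z")

    def test_grid_capped_by_quantiles(self, rng):
        vals = rng.normal(size=1000)
        grid = pdp_grid(vals, 100)
        assert len(grid) <= 100 and np.all(np.diff(grid) > 0)
        assert set(grid) <= set(vals)  # thinning keeps observed values

    def test_frequency_weighted_curve_mean_conserves_prediction_mean(self, rng):
        n = 120
        t = pd.DataFrame({"x": rng.integers(0, 8, n).astype(float)})
        t["y"] = t["x"] + rng.normal(scale=0.2, size=n)
        f = cs.fit_forest(t, ["x"], "y", SMALL)
        curve = cs.partial_dependence(f, t, "x")
        weights = np.array([(t["x"] == v).mean() for v in curve.grid])
        weighted = float(np.sum(weights * curve.marginal_predictions))
        assert weighted == pytest.approx(float(np.mean(f.predict(t))), abs=1e-9)


class TestClassifyFactor:
    def test_monotone_directions(self):
        grid = np.arange(10.0)
        up = cs.classify_factor(PDPCurve("v", grid, grid * 0.5))
        down = cs.classify_factor(PDPCurve("v", grid, -grid * 0.5))
        assert up.label == "protective" and up.correlation > 0
        assert down.label == "risk" and down.correlation < 0

    def test_constant_curve_indeterminate(self):
        out = cs.classify_factor(PDPCurve("v", np.arange(5.0), np.ones(5)))
        assert out.label == "indeterminate" and out.reason == "constant curve"

    def test_dead_zone_avoids_coin_flip_labels(self, rng):
        grid = np.arange(50.0)
        noise = rng.normal(scale=1.0, size=50)
        out = cs.classify_factor(PDPCurve("v", grid, noise), dead_zone=0.5)
        assert out.label == "indeterminate"


class TestThreshold:
    def test_monotone_curve_has_no_threshold(self):
        grid = np.arange(20.0)
        assert cs.detect_threshold(PDPCurve("v", grid, grid**1.5)) is None

    def test_symmetric_tent_peak_detected(self):
        curve = _tent(peak=420.0)
        got = cs.detect_threshold(curve)
        assert got == pytest.approx(420.0, abs=(curve.grid[1] - curve.grid[0]))

    def test_u_shaped_minimum_detected(self):
        curve = PDPCurve("v", np.arange(30.0), np.abs(np.arange(30.0) - 12))
        assert cs.detect_threshold(curve) == pytest.approx(12.0, abs=1.0)

    def test_invariant_under_monotone_grid_rescaling(self):
        curve = _tent(peak=420.0)
        scaled = PDPCurve("v", 2.0 * curve.grid + 5.0, curve.marginal_predictions)
        t0 = cs.detect_threshold(curve)
        t1 = cs.detect_threshold(scaled)
        assert t1 == pytest.approx(2.0 * t0 + 5.0)


class TestProtectiveRange:
    def test_half_range_geometry_of_tent(self):
        grid = np.arange(0.0, 101.0)
        curve = PDPCurve("v", grid, 50.0 - np.abs(grid - 50.0))
        lo, hi = cs.protective_range(curve, 50.0)
        assert lo == pytest.approx(25.0, abs=2.0)
        assert hi == pytest.approx(75.0, abs=2.0)

    def test_flat_top_spans_plateau(self):
        grid = np.arange(0.0, 101.0)
        vals = np.minimum(grid, 100.0 - grid)
        vals = np.minimum(vals, 30.0)  # plateau from 30 to 70
        curve = PDPCurve("v", grid, vals)
        lo, hi = cs.protective_range(curve, 50.0)
        assert lo <= 30.0 and hi >= 70.0


class TestSegmentedCorrelation:
    def test_coupling_above_breakpoint_only(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.uniform(0, 100, n)
        y = np.where(x > 50, -(x - 50) * 0.08, 0.0) + rng.normal(scale=0.8, size=n)
        t = pd.DataFrame({"conv": x, "steps": y})
        out = cs.segmented_correlation(t, "conv", "steps", 50.0)
        assert out["above"]["slope"] < 0 and out["above"]["p_value"] < 0.05
        assert out["below"]["p_value"] > 0.05

    def test_breakpoint_below_all_data_flags_insufficient(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"a": rng.uniform(10, 20, 50), "b": rng.normal(size=50)})
        out = cs.segmented_correlation(t, "a", "b", 10.0)
        assert out["below"]["insufficient"]
        assert not out["above"]["insufficient"]

    def test_invalid_breakpoint_units_rejected(self, rng):
        t = pd.DataFrame({"a": rng.uniform(10, 20, 50), "b": rng.normal(size=50)})
        with pytest.raises(ValueError, match="breakpoint_units"):
            cs.segmented_correlation(t, "a", "b", 15.0, breakpoint_units="minutes")
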