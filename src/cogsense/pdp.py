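"""Partial dependence, risk/protective classification, threshold detection.

The partial-dependence curve of a variable is computed by substituting each
grid value into every observation's column and averaging the forest's
predictions. A variable is *protective* when the Pearson correlation between
grid values and marginal predictions is positive, *risk* when negative; an
interior slope reversal of the smoothed curve yields a threshold, and the
half-range rule around the peak yields a protective range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forest import FittedForest

__all__ = [
    "PDPCurve",
    "FactorClassification",
    "partial_dependence",
    "classify_factor",
    "detect_threshold",
    "protective_range",
    "segmented_correlation",
]


@dataclass
class PDPCurve:
    """Grid of variable values with marginal model predictions."""

    variable: str
    grid: np.ndarray
    marginal_predictions: np.ndarray
    n_grid_cap: int = 256

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.marginal_predictions = np.asarray(self.marginal_predictions, dtype=float)
        if len(self.grid) != len(self.marginal_predictions):
            raise ValueError("grid and marginal_predictions must have equal length")
        if len(self.grid) > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")


@dataclass
class FactorClassification:
    """Risk/protective label for one variable, from its PDP curve."""

    variable: str
    correlation: float
    label: str  # "protective" | "risk" | "indeterminate"
    threshold: float | None = None
    protective_range: tuple[float, float] | None = None
    reason: str | None = None


def pdp_grid(values: np.ndarray, n_grid_cap: int = 256) -> np.ndarray:
    """Sorted unique observed values, quantile-thinned above the cap."""
    unique = np.unique(np.asarray(values, dtype=float))
    if len(unique) <= n_grid_cap:
        return unique
    qs = np.quantile(values, np.linspace(0.0, 1.0, n_grid_cap), method="nearest")
    return np.unique(qs)


def partial_dependence(
    forest: FittedForest,
    table: pd.DataFrame,
    variable: str,
    n_grid_cap: int = 256,
) -> PDPCurve:
    """Substitution-and-average partial dependence of ``variable``.

    For each grid value v, every observation's ``variable`` column is set to
    v, the forest predicts all rows, and the predictions are averaged.
    """
    if variable not in forest.predictors:
        raise ValueError(f"variable {variable!r} is not a model predictor")
    grid = pdp_grid(table[variable].to_numpy(), n_grid_cap)
    X = table[forest.predictors].to_numpy(dtype=float)
    col = forest.predictors.index(variable)
    n = len(X)
    preds = np.empty(len(grid))
    # Batch several grid values per predict call; per-row tree traversal and
    # the per-grid-value mean are unchanged by the batching.
    chunk = max(1, 2_000_000 // max(n, 1))
    for start in range(0, len(grid), chunk):
        vs = grid[start : start + chunk]
        tiled = np.tile(X, (len(vs), 1))
        tiled[:, col] = np.repeat(vs, n)
        block = forest.model.predict(tiled).reshape(len(vs), n)
        preds[start : start + chunk] = block.mean(axis=1)
    return PDPCurve(variable, grid, preds, n_grid_cap)


def classify_factor(curve: PDPCurve, dead_zone: float = 0.05) -> FactorClassification:
    """Label a variable by the sign of corr(grid, marginal predictions).

    Correlations inside the ``dead_zone`` (or a constant curve) are reported
    as indeterminate instead of assigning a coin-flip label.
    """
    if len(curve.grid) < 3:
        raise ValueError("need at least 3 grid points")
    if np.ptp(curve.marginal_predictions) == 0:
        return FactorClassification(curve.variable, float("nan"), "indeterminate",
                                    reason="constant curve")
    r, _ = stats.pearsonr(curve.grid, curve.marginal_predictions)
    r = float(r)
    if abs(r) < dead_zone:
        return FactorClassification(curve.variable, r, "indeterminate", reason="flat curve")
    return FactorClassification(curve.variable, r, "protective" if r > 0 else "risk")


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_threshold(curve: PDPCurve, smoothing_window: int = 5) -> float | None:
    """Grid location where the smoothed curve's slope reverses, if any.

    The curve is smoothed with a centred moving average; a global interior
    extremum qualifies as a threshold when the first differences keep one
    sign for >= 2 consecutive points before it and the opposite sign for
    >= 2 consecutive points after it. Monotone curves return None.
    """
    if len(curve.grid) < 5:
        raise ValueError("need at least 5 grid points")
    sm_vals = _smooth(curve.marginal_predictions, smoothing_window)
    diffs = np.diff(sm_vals)

    for extremum in ("max", "min"):
        vals = sm_vals if extremum == "max" else -sm_vals
        peak = vals.max()
        at_peak = np.flatnonzero(vals == peak)
        i, j = int(at_peak[0]), int(at_peak[-1])  # plateau span
        if i < 2 or j > len(sm_vals) - 3:
            continue
        before = diffs[i - 2 : i]
        after = diffs[j : j + 2]
        sign = 1.0 if extremum == "max" else -1.0
        if np.all(sign * before > 0) and np.all(sign * after < 0):
            return float(curve.grid[(i + j) // 2])
    return None


def protective_range(
    curve: PDPCurve, threshold: float, smoothing_window: int = 5
) -> tuple[float, float]:
    """Half-range interval around a detected peak, in variable units.

    The maximal contiguous grid interval containing the extremum on which
    the smoothed marginal prediction stays at or above
    ``min + 0.5 * (max - min)``.
    """
    sm_vals = _smooth(curve.marginal_predictions, smoothing_window)
    level = sm_vals.min() + 0.5 * np.ptp(sm_vals)
    center = int(np.argmin(np.abs(curve.grid - threshold)))
    above = sm_vals >= level
    if not above[center]:  # threshold was a minimum; use the band around the max
        center = int(np.argmax(sm_vals))
    lo = center
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = center
    while hi < len(above) - 1 and above[hi + 1]:
        hi += 1
    return float(curve.grid[lo]), float(curve.grid[hi])


def segmented_correlation(
    table: pd.DataFrame,
    x_variable: str,
    y_variable: str,
    breakpoint: float,
    breakpoint_units: str = "raw",
    min_side_n: int = 10,
) -> dict:
    """Piecewise linear association below/above a breakpoint.

    Both variables are rank-inverse-normal transformed first; the breakpoint
    may be given in raw variable units (mapped through the transform) or
    directly in transformed units. Each side with at least ``min_side_n``
    points gets a straight-line fit (slope, r, two-sided p); smaller sides
    are flagged insufficient.
    """
    from .contribution import normal_transform

    x_raw = table[x_variable].to_numpy(dtype=float)
    y_raw = table[y_variable].to_numpy(dtype=float)
    x = normal_transform(x_raw)
    y = normal_transform(y_raw)
    if breakpoint_units == "raw":
        if breakpoint < x_raw.min():
            cut = -np.inf  # below side empty -> flagged insufficient
        elif breakpoint > x_raw.max():
            cut = np.inf
        else:
            cut = x[np.argmin(np.abs(x_raw - breakpoint))]
    elif breakpoint_units == "transformed":
        cut = float(breakpoint)
    else:
        raise ValueError("breakpoint_units must be 'raw' or 'transformed'")

    out: dict = {"x_variable": x_variable, "y_variable": y_variable, "breakpoint": float(cut)}
    for side, mask in (("below", x <= cut), ("above", x > cut)):
        if int(mask.sum()) < min_side_n:
            out[side] = {"n": int(mask.sum()), "insufficient": True}
            continue
        fit = stats.linregress(x[mask], y[mask])
        out[side] = {
            "n": int(mask.sum()),
            "slope": float(fit.slope),
            "r": float(fit.rvalue),
            "p_value": float(fit.pvalue),
            "insufficient": False,
        }
    return out
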