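"""Per-variable contributions and linear-vs-forest prediction accuracy.

Selected lifestyle variables are rank-inverse-normal (Blom) transformed and
entered into a multiple linear regression on MMSE; the estimate sign labels
each variable risk (negative) or protective (positive) and its p-value gives
significance. A companion train/test comparison fits a linear model and a
regression forest on the same variable set and reports R2 / MSE / RMSE on
both halves of a 90/10 split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .forest import ForestSpec, fit_forest, train_test_split_indices

__all__ = [
    "ContributionReport",
    "AccuracyReport",
    "normal_transform",
    "contribution_regression",
    "compare_models",
]

TRANSFORM_NAME = "rank-based inverse normal (Blom)"


def normal_transform(values: np.ndarray) -> np.ndarray:
    """Blom rank-inverse-normal transform: Phi^-1((rank - 3/8) / (n + 1/4)).

    Ties receive average ranks; the output is strictly monotone in the input
    (up to ties) with sample mean ~0 and variance ~1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; ranks undefined")
    ranks = sps.rankdata(values, method="average")
    return sps.norm.ppf((ranks - 0.375) / (values.size + 0.25))


@dataclass
class ContributionReport:
    """Regression-based contribution of each selected variable."""

    transform: str
    estimates: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    standardized_estimates: dict[str, float]
    labels: dict[str, str] = field(default_factory=dict)  # risk | protective
    significant: dict[str, bool] = field(default_factory=dict)
    n: int = 0


def contribution_regression(
    table: pd.DataFrame,
    selected_variables: list[str],
    outcome: str = "mmse",
    alpha: float = 0.05,
) -> ContributionReport:
    """OLS of the outcome on Blom-transformed selected variables.

    Reports both the raw-scale estimates on the transformed predictors and
    fully standardized coefficients (outcome standardized too), since the
    transformed predictors are already near unit variance.
    """
    X = np.column_stack([normal_transform(table[v].to_numpy()) for v in selected_variables])
    y = table[outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError("design matrix rank deficient after transform")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["const"] + list(selected_variables)
    estimates = dict(zip(names, map(float, fit.params)))
    y_sd = float(np.std(y, ddof=1))
    standardized = {
        v: estimates[v] * float(np.std(normal_transform(table[v].to_numpy()), ddof=1)) / y_sd
        for v in selected_variables
    }
    p_values = dict(zip(names, map(float, fit.pvalues)))
    return ContributionReport(
        transform=TRANSFORM_NAME,
        estimates=estimates,
        std_errors=dict(zip(names, map(float, fit.bse))),
        t_values=dict(zip(names, map(float, fit.tvalues))),
        p_values=p_values,
        standardized_estimates=standardized,
        labels={v: ("protective" if estimates[v] > 0 else "risk") for v in selected_variables},
        significant={v: p_values[v] < alpha for v in selected_variables},
        n=int(fit.nobs),
    )


@dataclass
class AccuracyReport:
    """Train/test R2, MSE and RMSE for the linear and forest models."""

    split_seed: int
    metrics: dict[str, dict[str, float]]  # model -> {train_r2, ..., test_rmse}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics).T


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    resid = y_true - y_pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return {"r2": r2, "mse": mse, "rmse": float(np.sqrt(mse))}


def compare_models(
    table: pd.DataFrame,
    variables: list[str],
    outcome: str = "mmse",
    split_seed: int = 0,
    forest_spec: ForestSpec = ForestSpec(),
) -> AccuracyReport:
    """Fit linear and forest models on a 90% split; evaluate on both halves."""
    train_idx, test_idx = train_test_split_indices(len(table), split_seed)
    train, test = table.iloc[train_idx], table.iloc[test_idx]

    Xtr = sm.add_constant(train[variables].to_numpy(dtype=float))
    ytr = train[outcome].to_numpy(dtype=float)
    linear = sm.OLS(ytr, Xtr).fit()
    Xte = sm.add_constant(test[variables].to_numpy(dtype=float), has_constant="add")

    forest = fit_forest(train, variables, outcome, forest_spec)

    metrics = {
        "linear": {},
        "forest": {},
    }
    for split_name, frame, Xlin in (("train", train, Xtr), ("test", test, Xte)):
        y = frame[outcome].to_numpy(dtype=float)
        for model_name, pred in (
            ("linear", np.asarray(linear.predict(Xlin))),
            ("forest", forest.predict(frame)),
        ):
            for key, val in _metrics(y, pred).items():
                metrics[model_name][f"{split_name}_{key}"] = val
    return AccuracyReport(split_seed=split_seed, metrics=metrics)
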