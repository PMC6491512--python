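"""Nested linear models and coefficient-change confounder screening.

Three nested OLS models regress MMSE on the lifestyle variables: model 0
unadjusted, model 1 additionally adjusted for age, gender and education, and
model 2 further adjusted for BMI, smoking, alcohol and the vascular
comorbidities. Confounding influence on a lifestyle variable is quantified
as the percentage change of its coefficient between the unadjusted and
adjusted fits, ``100 * (adjusted - unadjusted) / unadjusted``; a variable is
flagged as influenced when |change| > 200%, when the coefficient's sign
reverses, or when it is newly added (enters the adjusted model's selected
set without having been selected unadjusted). Influenced variables are
excluded from the adjusted models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .variables import ADJUSTMENT_SETS

__all__ = [
    "CoefficientChange",
    "LinearFit",
    "fit_linear_model",
    "coefficient_changes",
    "exclude_influenced",
    "screen_confounding",
]


@dataclass
class LinearFit:
    """OLS coefficients with standard errors and two-sided p-values."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    n: int
    variables: list[str]


@dataclass
class CoefficientChange:
    """Confounding diagnostics for one lifestyle variable."""

    variable: str
    unadjusted_coef: float | None
    adjusted_coef: float | None
    percent_change: float | None  # None when the unadjusted coefficient is 0 or absent
    sign_reversed: bool
    newly_added: bool

    @property
    def influenced(self) -> bool:
        big_change = self.percent_change is not None and abs(self.percent_change) > 200.0
        return big_change or self.sign_reversed or self.newly_added

    @property
    def reasons(self) -> list[str]:
        out = []
        if self.percent_change is not None and abs(self.percent_change) > 200.0:
            out.append("percent_change")
        if self.sign_reversed:
            out.append("sign_reversed")
        if self.newly_added:
            out.append("newly_added")
        return out


def fit_linear_model(
    table: pd.DataFrame,
    lifestyle_variables: list[str],
    adjustment_set: list[str],
    outcome: str = "mmse",
) -> LinearFit:
    """OLS of the outcome on lifestyle variables plus adjusters."""
    variables = list(lifestyle_variables) + [v for v in adjustment_set if v not in lifestyle_variables]
    X = table[variables].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < len(variables) + 1:
        corr = np.corrcoef(X, rowvar=False)
        collinear = [
            f"{variables[i]}~{variables[j]}"
            for i in range(len(variables))
            for j in range(i + 1, len(variables))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"design matrix rank deficient; collinear columns: {collinear or 'unknown'}")
    design = sm.add_constant(X)
    fit = sm.OLS(table[outcome].to_numpy(dtype=float), design).fit()
    names = ["const"] + variables
    return LinearFit(
        coefficients=dict(zip(names, map(float, fit.params))),
        std_errors=dict(zip(names, map(float, fit.bse))),
        t_values=dict(zip(names, map(float, fit.tvalues))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
        n=int(fit.nobs),
        variables=variables,
    )


def coefficient_changes(
    model0_fit: LinearFit,
    adjusted_fit: LinearFit,
    selected0: list[str],
    selected_adjusted: list[str],
) -> list[CoefficientChange]:
    """Per-variable coefficient-change diagnostics between nested fits.

    ``selected0`` / ``selected_adjusted`` are the variable sets chosen by the
    unadjusted and adjusted selection stage; a variable present only in the
    adjusted set is ``newly_added`` (fixed-covariate linear fits cannot add
    variables on their own).
    """
    changes = []
    for var in selected_adjusted:
        newly = var not in selected0
        unadj = model0_fit.coefficients.get(var)
        adj = adjusted_fit.coefficients.get(var)
        if adj is None:
            raise ValueError(f"variable {var!r} missing from the adjusted fit")
        if newly or unadj is None:
            changes.append(CoefficientChange(var, unadj, adj, None, False, newly))
            continue
        if unadj == 0.0:
            pct = None  # undefined; evaluate on sign reversal only
        else:
            pct = 100.0 * (adj - unadj) / unadj
        reversed_ = bool(unadj * adj < 0)
        changes.append(CoefficientChange(var, unadj, adj, pct, reversed_, False))
    return changes


def exclude_influenced(
    selected_variables: list[str], changes: list[CoefficientChange]
) -> tuple[list[str], dict[str, list[str]]]:
    """Drop influenced variables; return survivors and per-variable reasons."""
    by_var = {c.variable: c for c in changes}
    surviving, reasons = [], {}
    for var in selected_variables:
        change = by_var.get(var)
        if change is not None and change.influenced:
            reasons[var] = change.reasons
        else:
            surviving.append(var)
    return surviving, reasons


def screen_confounding(
    table: pd.DataFrame,
    selected0: list[str],
    selected_adjusted: list[str],
    model_id: int,
    outcome: str = "mmse",
) -> dict:
    """Full screen of one adjusted model against the unadjusted baseline.

    Fits the model-0 regression on the unadjusted selected lifestyle set and
    the adjusted regression on the adjusted selected set plus that model's
    adjustment covariates, computes the coefficient changes, and excludes the
    influenced variables.
    """
    if model_id not in (1, 2):
        raise ValueError("model_id must be 1 or 2 for an adjusted screen")
    adjusters = ADJUSTMENT_SETS[model_id]
    lifestyle_adjusted = [v for v in selected_adjusted if v not in adjusters]
    fit0 = fit_linear_model(table, selected0, [], outcome)
    fit_adj = fit_linear_model(table, lifestyle_adjusted, adjusters, outcome)
    changes = coefficient_changes(fit0, fit_adj, selected0, lifestyle_adjusted)
    surviving, reasons = exclude_influenced(lifestyle_adjusted, changes)
    return {
        "model_id": model_id,
        "fit0": fit0,
        "fit_adjusted": fit_adj,
        "changes": changes,
        "surviving": surviving,
        "excluded": reasons,
    }
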