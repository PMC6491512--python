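"""End-to-end analysis: selection -> confounding screen -> PDP -> report.

``run_analysis`` strings the stages together on an assembled feature table,
mirroring the study design: rank and select variables with a regression
forest per adjustment model, screen the adjusted selections for confounding
against the unadjusted baseline, classify the surviving lifestyle variables
as risk/protective from their partial-dependence curves, quantify their
contributions by linear regression on transformed variables, and compare
linear vs forest prediction accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import confounding as conf
from . import contribution as contrib
from . import pdp as pdp_mod
from .forest import FittedForest, ForestSpec, fit_forest, importance_ranking, topn_select
from .variables import ADJUSTMENT_SETS, DEMOGRAPHIC_ADJUSTERS, MODEL_POOLS, OUTCOME

__all__ = ["ModelResult", "AnalysisResult", "select_variables", "run_analysis"]


@dataclass
class ModelResult:
    """Everything computed for one adjustment model."""

    model_id: int
    selection: "object"
    screen: dict | None = None
    surviving: list[str] = field(default_factory=list)
    pdp_forest: FittedForest | None = None
    classifications: dict[str, pdp_mod.FactorClassification] = field(default_factory=dict)
    curves: dict[str, pdp_mod.PDPCurve] = field(default_factory=dict)


@dataclass
class AnalysisResult:
    models: dict[int, ModelResult]
    contribution: contrib.ContributionReport | None
    accuracy: contrib.AccuracyReport | None


def select_variables(
    table: pd.DataFrame,
    model_id: int,
    spec: ForestSpec = ForestSpec(),
    split_seed: int = 0,
    n_splits: int = 1,
):
    """Importance ranking and top-N selection on one model's predictor pool."""
    pool = MODEL_POOLS[model_id]
    forest = fit_forest(table, pool, OUTCOME, spec)
    ranking = importance_ranking(forest)
    return topn_select(
        table, ranking, OUTCOME, spec, split_seed=split_seed, model_id=model_id, n_splits=n_splits
    )


def run_analysis(
    table: pd.DataFrame,
    spec: ForestSpec = ForestSpec(),
    split_seed: int = 0,
    model_ids: tuple[int, ...] = (0, 1, 2),
    pdp_model: int = 1,
    n_grid_cap: int = 256,
) -> AnalysisResult:
    """Run the full pipeline on an eligible feature table."""
    models: dict[int, ModelResult] = {}
    for mid in model_ids:
        sel = select_variables(table, mid, spec, split_seed)
        models[mid] = ModelResult(model_id=mid, selection=sel)

    selected0 = models[0].selection.selected_variables if 0 in models else []
    for mid, result in models.items():
        if mid == 0:
            result.surviving = list(result.selection.selected_variables)
            continue
        screen = conf.screen_confounding(
            table, selected0, result.selection.selected_variables, mid
        )
        result.screen = screen
        result.surviving = screen["surviving"]

    # PDP stage on the chosen adjustment model's surviving variables.
    target = models.get(pdp_model)
    surviving = target.surviving if target else []
    if target and surviving:
        predictors = surviving + [v for v in ADJUSTMENT_SETS.get(pdp_model, []) if v not in surviving]
        pdp_forest = fit_forest(table, predictors, OUTCOME, spec)
        target.pdp_forest = pdp_forest
        for var in surviving:
            curve = pdp_mod.partial_dependence(pdp_forest, table, var, n_grid_cap)
            cls = pdp_mod.classify_factor(curve)
            if len(curve.grid) >= 5:
                cls.threshold = pdp_mod.detect_threshold(curve)
                if cls.threshold is not None:
                    cls.protective_range = pdp_mod.protective_range(curve, cls.threshold)
            target.curves[var] = curve
            target.classifications[var] = cls

    contribution = None
    accuracy = None
    if surviving:
        contribution = contrib.contribution_regression(table, surviving)
        acc_vars = surviving + [v for v in DEMOGRAPHIC_ADJUSTERS if v not in surviving]
        accuracy = contrib.compare_models(table, acc_vars, OUTCOME, split_seed, spec)
    return AnalysisResult(models=models, contribution=contribution, accuracy=accuracy)
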