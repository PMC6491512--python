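"""Random-forest importance ranking and top-N variable selection.

A regression forest (500 trees, ``mtry = floor(p/3)`` candidate variables
per split, bootstrap bags) is fit to the full table to rank predictors by
node-impurity importance (total decrease in node sum-of-squares, the
IncNodePurity convention). The top-N subset is then chosen as the N whose
forest, trained on a random 90% of rows, minimises RMSE on the held-out 10%.
Hyperparameters are deliberately not tuned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .variables import table_order_key

__all__ = ["ForestSpec", "FittedForest", "SelectionResult", "fit_forest",
           "importance_ranking", "topn_select", "rmse", "default_mtry"]


def default_mtry(p: int) -> int:
    """The regression-forest default: floor(p/3), at least 1."""
    return max(p // 3, 1)


@dataclass(frozen=True)
class ForestSpec:
    """Forest hyperparameters (untuned defaults)."""

    ntree: int = 500
    mtry: int | None = None  # None -> floor(p/3)
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else default_mtry(p)
        if not 1 <= m <= p:
            raise ValueError(f"mtry must be in [1, {p}], got {m}")
        return m


@dataclass
class FittedForest:
    """Opaque predictor handle wrapping the fitted ensemble."""

    model: RandomForestRegressor
    predictors: list[str]
    outcome: str
    degenerate: bool = False  # constant outcome

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(table[self.predictors].to_numpy())


@dataclass
class SelectionResult:
    """Importance ranking plus the RMSE-minimising top-N subset."""

    model_id: int
    ranking: list[tuple[str, float]]
    rmse_by_n: dict[int, float]
    chosen_n: int
    selected_variables: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "ranking": [[v, float(i)] for v, i in self.ranking],
            "rmse_by_n": {int(k): float(v) for k, v in self.rmse_by_n.items()},
            "chosen_n": int(self.chosen_n),
            "selected_variables": list(self.selected_variables),
        }


def fit_forest(
    table: pd.DataFrame,
    predictors: list[str],
    outcome: str,
    spec: ForestSpec = ForestSpec(),
) -> FittedForest:
    """Fit a bagged regression forest; reproducible under a fixed seed."""
    missing = [v for v in predictors if v not in table.columns]
    if missing:
        raise ValueError(f"predictors not in table: {missing}")
    if len(table) < 10:
        raise ValueError(f"need n >= 10 rows, got {len(table)}")
    X = table[list(predictors)].to_numpy()
    y = table[outcome].to_numpy(dtype=float)
    model = RandomForestRegressor(
        n_estimators=spec.ntree,
        max_features=spec.resolve_mtry(len(predictors)),
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return FittedForest(model, list(predictors), outcome, degenerate=bool(np.ptp(y) == 0))


def importance_ranking(forest: FittedForest) -> list[tuple[str, float]]:
    """Predictors ordered by decreasing node-impurity importance.

    Ties are broken by canonical table column order so the ranking is
    deterministic.
    """
    imp = forest.model.feature_importances_
    pairs = list(zip(forest.predictors, map(float, imp)))
    return sorted(pairs, key=lambda vi: (-vi[1], table_order_key(vi[0])))


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root mean squared error."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {observed.shape}")
    if predicted.size == 0:
        raise ValueError("need n >= 1")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def train_test_split_indices(
    n: int, split_seed: int, test_fraction: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Single stratification-free random split (shared convention)."""
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n - n_test < 1:
        raise ValueError(f"n={n} too small for a {test_fraction:.0%} test split")
    perm = np.random.default_rng(split_seed).permutation(n)
    return perm[n_test:], perm[:n_test]


def topn_select(
    table: pd.DataFrame,
    ranking: list[tuple[str, float]],
    outcome: str,
    spec: ForestSpec = ForestSpec(),
    split_seed: int = 0,
    model_id: int = 0,
    n_splits: int = 1,
) -> SelectionResult:
    """Choose the top-N subset minimising held-out RMSE.

    Uses a single random 90/10 split by default; ``n_splits > 1`` switches to
    the median RMSE over repeated splits (lower-variance variant). Ties in
    RMSE resolve to the smallest N.
    """
    variables = [v for v, _ in ranking]
    p = len(variables)
    rmse_by_n: dict[int, float] = {}
    for n_top in range(1, p + 1):
        cols = variables[:n_top]
        vals = []
        for s in range(n_splits):
            train_idx, test_idx = train_test_split_indices(len(table), split_seed + s)
            train, test = table.iloc[train_idx], table.iloc[test_idx]
            sub_spec = ForestSpec(spec.ntree, spec.mtry, spec.seed)
            forest = fit_forest(train, cols, outcome, sub_spec)
            vals.append(rmse(forest.predict(test), test[outcome].to_numpy()))
        rmse_by_n[n_top] = float(np.median(vals))
    chosen_n = min(rmse_by_n, key=lambda n_top: (rmse_by_n[n_top], n_top))
    return SelectionResult(
        model_id=model_id,
        ranking=list(ranking),
        rmse_by_n=rmse_by_n,
        chosen_n=chosen_n,
        selected_variables=variables[:chosen_n],
    )
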