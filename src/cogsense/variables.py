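"""Canonical variable names, model pools, and adjustment sets.

The analysis table has 17 predictors (nine demographic/clinical covariates
and eight wearable-sensor lifestyle features) plus the MMSE outcome. Column
order below is the canonical table order and is used to break importance
ties deterministically.
"""

from __future__ import annotations

#: Eight per-day lifestyle features scored from the wristband sensor.
LIFESTYLE_VARIABLES: list[str] = [
    "walking_steps",
    "conversation_time",
    "heart_rate",
    "tst",
    "waso",
    "sleep_efficiency",
    "awakening_count",
    "nap_time",
]

#: Demographic covariates used by the first adjusted model.
DEMOGRAPHIC_ADJUSTERS: list[str] = ["age", "gender", "education"]

#: Additional vascular/behavioural covariates used by the fully adjusted model.
VASCULAR_ADJUSTERS: list[str] = [
    "bmi",
    "smoking",
    "alcohol",
    "hypertension",
    "diabetes",
    "hypercholesterolemia",
]

#: All 17 predictors in canonical table order.
TABLE_COLUMNS: list[str] = DEMOGRAPHIC_ADJUSTERS + VASCULAR_ADJUSTERS + LIFESTYLE_VARIABLES

OUTCOME: str = "mmse"

#: Predictor pool handed to the random-forest variable selection, per model.
#: Model 0 ranks the sensor features alone; model 1 adds the demographic
#: covariates; model 2 uses all 17 predictors.
MODEL_POOLS: dict[int, list[str]] = {
    0: list(LIFESTYLE_VARIABLES),
    1: DEMOGRAPHIC_ADJUSTERS + LIFESTYLE_VARIABLES,
    2: TABLE_COLUMNS,
}

#: Covariates entered as fixed adjusters in the nested linear models.
ADJUSTMENT_SETS: dict[int, list[str]] = {
    0: [],
    1: list(DEMOGRAPHIC_ADJUSTERS),
    2: DEMOGRAPHIC_ADJUSTERS + VASCULAR_ADJUSTERS,
}


def table_order_key(variable: str) -> int:
    """Position of ``variable`` in the canonical table order (ties fallback)."""
    try:
        return TABLE_COLUMNS.index(variable)
    except ValueError:
        return len(TABLE_COLUMNS)
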