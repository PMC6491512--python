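"""Cohort assembly: eligibility rules, feature averaging, validation metrics.

The analysis table has one row per eligible participant: demographic and
clinical covariates, the eight lifestyle features averaged over valid sensor
days, and the MMSE outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .variables import LIFESTYLE_VARIABLES, TABLE_COLUMNS

__all__ = [
    "apply_eligibility",
    "average_features",
    "build_feature_table",
    "eligible_table",
    "compute_bmi",
    "f_measure",
    "detection_metrics",
    "false_detection_rate",
    "validation_correlation",
]

#: Daily-feature column -> analysis-table column.
DAILY_TO_TABLE = {
    "steps": "walking_steps",
    "conversation_min": "conversation_time",
    "heart_rate": "heart_rate",
    "tst": "tst",
    "waso": "waso",
    "efficiency": "sleep_efficiency",
    "awakening_count": "awakening_count",
    "nap_min": "nap_time",
}


def apply_eligibility(
    participants: pd.DataFrame,
    daily_features: pd.DataFrame | None = None,
    min_valid_days: int = 7,
    min_age: float = 65.0,
    min_mmse: int = 20,
) -> pd.DataFrame:
    """Flag each participant eligible/ineligible with reason codes.

    Exclusions: age below ``min_age``, MMSE below ``min_mmse``, a truthy
    ``clinical_exclusion`` column, and (when ``daily_features`` is given)
    fewer than ``min_valid_days`` valid sensor days. Returns the participant
    table with ``eligible``, ``exclusion_reasons`` and ``n_valid_days``
    columns appended.
    """
    if participants["participant_id"].duplicated().any():
        dupes = participants.loc[participants["participant_id"].duplicated(), "participant_id"]
        raise ValueError(f"duplicate participant_id values: {sorted(set(dupes))}")
    out = participants.copy()
    reasons: list[list[str]] = [[] for _ in range(len(out))]

    age = out["age"].to_numpy()
    mmse = out["mmse"].to_numpy()
    for i in range(len(out)):
        if age[i] < min_age:
            reasons[i].append("age")
        if mmse[i] < min_mmse:
            reasons[i].append("mmse")
    if "clinical_exclusion" in out.columns:
        for i, flag in enumerate(out["clinical_exclusion"].to_numpy()):
            if flag:
                reasons[i].append("clinical")

    if daily_features is not None:
        valid = daily_features[daily_features["valid"]]
        counts = valid.groupby("participant_id").size()
        n_valid = out["participant_id"].map(counts).fillna(0).astype(int)
        for i, c in enumerate(n_valid):
            if c < min_valid_days:
                reasons[i].append("insufficient_days")
        out["n_valid_days"] = n_valid.to_numpy()

    out["exclusion_reasons"] = [",".join(r) for r in reasons]
    out["eligible"] = [not r for r in reasons]
    return out


def average_features(daily_features: pd.DataFrame) -> pd.DataFrame:
    """Per-participant arithmetic means of the daily features over valid days.

    Returns one row per participant with the analysis-table feature names and
    a ``n_valid_days`` column. Order of the input days is immaterial.
    """
    valid = daily_features[daily_features["valid"]]
    grouped = valid.groupby("participant_id")[list(DAILY_TO_TABLE)].mean()
    grouped = grouped.rename(columns=DAILY_TO_TABLE)
    grouped["n_valid_days"] = valid.groupby("participant_id").size()
    return grouped.reset_index()


def build_feature_table(
    participants: pd.DataFrame,
    daily_features: pd.DataFrame,
    min_valid_days: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the 17-variable analysis table for eligible participants.

    Returns ``(table, exclusions)``: the table in canonical column order plus
    ``mmse``, and a log of excluded participants with their reason codes.
    Rows with missing model columns are dropped (and logged as
    ``missing_covariate``).
    """
    flagged = apply_eligibility(participants, daily_features, min_valid_days=min_valid_days)
    means = average_features(daily_features)
    merged = flagged.merge(means, on="participant_id", how="left")

    model_cols = TABLE_COLUMNS + ["mmse"]
    missing = merged[model_cols].isna().any(axis=1) & merged["eligible"]
    merged.loc[missing, "exclusion_reasons"] = merged.loc[missing, "exclusion_reasons"].where(
        merged.loc[missing, "exclusion_reasons"] != "", "missing_covariate"
    )
    merged.loc[missing, "eligible"] = False

    excluded = merged.loc[~merged["eligible"], ["participant_id", "exclusion_reasons"]]
    table = merged.loc[merged["eligible"], ["participant_id"] + model_cols].reset_index(drop=True)
    return table, excluded.reset_index(drop=True)


def eligible_table(table: pd.DataFrame, min_age: float = 65.0, min_mmse: int = 20) -> pd.DataFrame:
    """Apply the age/MMSE inclusion rules to an already-assembled table."""
    keep = (table["age"] >= min_age) & (table["mmse"] >= min_mmse)
    return table.loc[keep].reset_index(drop=True)


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index: weight in kilograms divided by height in metres squared."""
    if height_m <= 0:
        raise ValueError("height_m must be > 0")
    return weight_kg / height_m**2


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def detection_metrics(predicted: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Minute-level precision / recall / F-measure of binary event detection.

    Denominator-free cases are reported as NaN rather than silently zeroed.
    """
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    tp = float(np.sum(predicted & truth))
    fp = float(np.sum(predicted & ~truth))
    fn = float(np.sum(~predicted & truth))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure(precision, recall),
    }


def false_detection_rate(
    detected_minutes: np.ndarray, n_items: int | None = None, minutes_per_item: float = 100.0
) -> float:
    """Fraction of non-conversation sound time wrongly detected as conversation.

    ``sum(detected) / (n_items * minutes_per_item)``, with ``n_items``
    defaulting to the number of sound items supplied.
    """
    detected = np.asarray(detected_minutes, dtype=float)
    if (detected < 0).any():
        raise ValueError("detected_minutes must be nonnegative")
    if n_items is None:
        n_items = len(detected)
    if n_items < 1 or minutes_per_item <= 0:
        raise ValueError("n_items must be >= 1 and minutes_per_item > 0")
    return float(detected.sum() / (n_items * minutes_per_item))


def validation_correlation(sensor_values: np.ndarray, reference_values: np.ndarray) -> dict:
    """Pearson correlation between sensor and reference measurements."""
    x = np.asarray(sensor_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length sequences with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p_value": float("nan"), "undefined": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "undefined": False}
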