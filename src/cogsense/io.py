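"""CSV dialects for the pipeline's on-disk interfaces.

Epoch CSV: one row per minute epoch — participant_id, date (ISO-8601),
minute_of_day (0-1439), movement, steps, sound_frames, pulses.
Participant CSV: demographics/comorbidity codes plus mmse.
Daily-features CSV: one row per scored participant-day.
Ground-truth CSV: the generator's per-day layout, for round-trip tests.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

EPOCH_COLUMNS = [
    "participant_id", "date", "minute_of_day", "movement", "steps", "sound_frames", "pulses",
]
PARTICIPANT_COLUMNS = [
    "participant_id", "age", "gender", "education", "bmi", "smoking", "alcohol",
    "hypertension", "diabetes", "hypercholesterolemia", "mmse",
]
GROUND_TRUTH_COLUMNS = [
    "participant_id", "date", "sleep_onset_min", "sleep_end_min", "tst_min", "waso_min",
    "awakening_count", "nap_min", "conversation_min", "steps", "nonwear", "heart_rate",
]


def _write(df: pd.DataFrame, path: str | Path, columns: list[str] | None) -> None:
    if columns is not None:
        df = df[columns]
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def write_epochs(epochs: pd.DataFrame, path: str | Path) -> None:
    _write(epochs, path, EPOCH_COLUMNS)


def read_epochs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df[EPOCH_COLUMNS]


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    _write(participants, path, PARTICIPANT_COLUMNS)


def read_participants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)[PARTICIPANT_COLUMNS]


def write_daily_features(daily: pd.DataFrame, path: str | Path) -> None:
    _write(daily, path, None)


def read_daily_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    _write(truth, path, GROUND_TRUTH_COLUMNS)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])[GROUND_TRUTH_COLUMNS]
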