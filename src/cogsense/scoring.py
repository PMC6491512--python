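"""Minute-epoch scoring of daily lifestyle features.

Event definitions (all on 1-minute epochs):

* **Wear** — minutes inside any run of >= ``nonwear_run_min`` consecutive
  zero-pulse minutes are treated as sensor-off.
* **Sleep** — scored in the nocturnal window 18:00 -> 5:59 anchored to the
  evening's date. Sleep onset is the start of the first run of >= 20
  consecutive motionless minutes; sleep end is the last minute of the last
  such run. WASO is the total of moving minutes strictly inside the sleep
  interval, an awakening is a run of >= 20 consecutive moving minutes inside
  it, TST = (sleep end - sleep onset) - WASO, and efficiency = TST / time in
  bed.
* **Nap** — total minutes in motionless runs of >= ``nap_block_min`` between
  6:00 and 17:59.
* **Conversation** — worn minutes with >= ``conversation_min_frames`` voice
  sound frames ("more than four frames per minute"; set to 4 for the
  inclusive reading).
* **Steps / heart rate** — steps are summed and pulses averaged over worn
  minutes of the calendar day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoringParams",
    "SleepSummary",
    "detect_wear",
    "score_sleep",
    "score_nap",
    "score_conversation",
    "summarize_day",
    "score_cohort",
]

DAY_MINUTES = 1440
WINDOW_START = 1080  # 18:00
WINDOW_MINUTES = 720
DAYTIME_START, DAYTIME_END = 360, 1080


@dataclass(frozen=True)
class ScoringParams:
    """Tunable scoring thresholds (defaults follow the event definitions)."""

    motionless_eps: float = 0.0  # movement <= eps counts as "no movement"
    sleep_block_min: int = 20
    awakening_min: int = 20
    nap_block_min: int = 20
    conversation_min_frames: int = 5
    nonwear_run_min: int = 60
    min_worn_minutes: int = 1080  # valid-day rule


@dataclass
class SleepSummary:
    """Sleep scoring of one 18:00->5:59 window (minutes from 18:00)."""

    sleep_onset: int | None
    sleep_end: int | None
    tst: float
    waso: float
    efficiency: float | None
    awakening_count: int
    complete: bool = True

    @property
    def time_in_bed(self) -> float:
        if self.sleep_onset is None:
            return 0.0
        return float(self.sleep_end - self.sleep_onset)


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of the True runs of a boolean array."""
    padded = np.diff(np.r_[0, mask.astype(np.int8), 0])
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return starts, ends - starts


def detect_wear(pulses: np.ndarray, nonwear_run_min: int = 60) -> np.ndarray:
    """Worn mask per minute: long zero-pulse runs mark the sensor as removed."""
    pulses = np.asarray(pulses)
    worn = np.ones(pulses.shape, dtype=bool)
    starts, lengths = _runs(pulses == 0)
    for s, ln in zip(starts, lengths):
        if ln >= nonwear_run_min:
            worn[s : s + ln] = False
    return worn


def score_sleep(
    movement: np.ndarray,
    worn: np.ndarray,
    params: ScoringParams = ScoringParams(),
    complete: bool = True,
) -> SleepSummary:
    """Score one nocturnal window (arrays indexed in minutes from 18:00)."""
    movement = np.asarray(movement, dtype=float)
    worn = np.asarray(worn, dtype=bool)
    motionless = worn & (np.nan_to_num(movement, nan=np.inf) <= params.motionless_eps)

    starts, lengths = _runs(motionless)
    qual = lengths >= params.sleep_block_min
    if not qual.any():
        return SleepSummary(None, None, 0.0, 0.0, None, 0, complete)
    q_starts, q_lengths = starts[qual], lengths[qual]
    onset = int(q_starts[0])
    end = int(q_starts[-1] + q_lengths[-1] - 1)

    inside = slice(onset + 1, end)
    moving_inside = worn[inside] & ~motionless[inside]
    waso = float(np.sum(moving_inside))
    a_starts, a_lengths = _runs(moving_inside)
    awakenings = int(np.sum(a_lengths >= params.awakening_min))

    tib = float(end - onset)
    tst = tib - waso
    efficiency = tst / tib if tib > 0 else None
    return SleepSummary(onset, end, tst, waso, efficiency, awakenings, complete)


def score_nap(
    movement: np.ndarray, worn: np.ndarray, params: ScoringParams = ScoringParams()
) -> float:
    """Total daytime minutes inside motionless runs of >= ``nap_block_min``."""
    movement = np.asarray(movement, dtype=float)
    worn = np.asarray(worn, dtype=bool)
    motionless = worn & (np.nan_to_num(movement, nan=np.inf) <= params.motionless_eps)
    _, lengths = _runs(motionless)
    return float(lengths[lengths >= params.nap_block_min].sum())


def score_conversation(
    sound_frames: np.ndarray, worn: np.ndarray, params: ScoringParams = ScoringParams()
) -> float:
    """Count worn minutes whose sound-frame count reaches the voice threshold."""
    sound_frames = np.asarray(sound_frames)
    worn = np.asarray(worn, dtype=bool)
    return float(np.sum(worn & (sound_frames >= params.conversation_min_frames)))


def summarize_day(
    steps: np.ndarray,
    pulses: np.ndarray,
    worn: np.ndarray,
    sleep: SleepSummary,
    nap_min: float,
    conversation_min: float,
    params: ScoringParams = ScoringParams(),
) -> dict:
    """Assemble the daily feature record from the scored components."""
    worn = np.asarray(worn, dtype=bool)
    worn_minutes = int(worn.sum())
    heart_rate = float(np.mean(np.asarray(pulses)[worn])) if worn_minutes else np.nan
    valid = worn_minutes >= params.min_worn_minutes and sleep.complete
    return {
        "steps": float(np.asarray(steps)[worn].sum()),
        "conversation_min": conversation_min,
        "heart_rate": heart_rate,
        "tst": sleep.tst,
        "waso": sleep.waso,
        "efficiency": sleep.efficiency if sleep.efficiency is not None else np.nan,
        "awakening_count": sleep.awakening_count,
        "sleep_onset": sleep.sleep_onset if sleep.sleep_onset is not None else np.nan,
        "sleep_end": sleep.sleep_end if sleep.sleep_end is not None else np.nan,
        "nap_min": nap_min,
        "worn_minutes": worn_minutes,
        "sleep_complete": sleep.complete,
        "valid": bool(valid),
    }


def _day_arrays(day_df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Reindex one calendar day's epochs onto minutes 0..1439."""
    day_df = day_df.sort_values("minute_of_day")
    out = {
        "movement": np.full(DAY_MINUTES, np.nan),
        "steps": np.zeros(DAY_MINUTES),
        "sound_frames": np.zeros(DAY_MINUTES, dtype=int),
        "pulses": np.zeros(DAY_MINUTES, dtype=int),
        "present": np.zeros(DAY_MINUTES, dtype=bool),
    }
    minutes = day_df["minute_of_day"].to_numpy().astype(int)
    out["movement"][minutes] = day_df["movement"].to_numpy()
    out["steps"][minutes] = day_df["steps"].to_numpy()
    out["sound_frames"][minutes] = day_df["sound_frames"].to_numpy()
    out["pulses"][minutes] = day_df["pulses"].to_numpy()
    out["present"][minutes] = True
    return out


def score_cohort(epochs: pd.DataFrame, params: ScoringParams = ScoringParams()) -> pd.DataFrame:
    """Score every participant-day of an epoch stream.

    The nocturnal window of date *d* spans 18:00 of *d* through 5:59 of
    *d*+1; when the following morning is absent the window is scored on the
    available minutes and flagged incomplete. Scoring is insensitive to epoch
    row order. Days whose daytime half (a full 1440-epoch calendar day) is
    missing, e.g. the trailing morning emitted for the last window, are
    dropped.
    """
    records = []
    for pid, pdf in epochs.groupby("participant_id", sort=True):
        days = {date: _day_arrays(g) for date, g in pdf.groupby("date", sort=True)}
        worn_by_day = {
            date: arrs["present"] & detect_wear(arrs["pulses"], params.nonwear_run_min)
            for date, arrs in days.items()
        }
        for date, arrs in days.items():
            if int(arrs["present"].sum()) < DAY_MINUTES:
                continue  # partial (window-completion) day, not a scheduled day
            nxt = date + pd.Timedelta(days=1)
            if nxt in days:
                win_move = np.r_[days[date]["movement"][WINDOW_START:], days[nxt]["movement"][: WINDOW_MINUTES // 2]]
                win_worn = np.r_[worn_by_day[date][WINDOW_START:], worn_by_day[nxt][: WINDOW_MINUTES // 2]]
                complete = bool(days[nxt]["present"][: WINDOW_MINUTES // 2].all())
            else:
                win_move = days[date]["movement"][WINDOW_START:]
                win_worn = worn_by_day[date][WINDOW_START:]
                complete = False
            sleep = score_sleep(win_move, win_worn, params, complete=complete)
            nap = score_nap(
                arrs["movement"][DAYTIME_START:DAYTIME_END],
                worn_by_day[date][DAYTIME_START:DAYTIME_END],
                params,
            )
            conv = score_conversation(arrs["sound_frames"], worn_by_day[date], params)
            rec = summarize_day(
                arrs["steps"], arrs["pulses"], worn_by_day[date], sleep, nap, conv, params
            )
            rec["participant_id"] = pid
            rec["date"] = date
            records.append(rec)
    cols = [
        "participant_id",
        "date",
        "steps",
        "conversation_min",
        "heart_rate",
        "tst",
        "waso",
        "efficiency",
        "awakening_count",
        "sleep_onset",
        "sleep_end",
        "nap_min",
        "worn_minutes",
        "sleep_complete",
        "valid",
    ]
    return pd.DataFrame(records, columns=cols)
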