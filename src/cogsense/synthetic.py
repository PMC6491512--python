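"""Synthetic cohort generator with known ground truth.

Two levels of fidelity share one participant/effect model:

* :func:`generate_epoch_streams` writes minute-epoch sensor streams
  (movement magnitude, step count, voice sound-frame count, pulse count) with
  a recorded per-day ground-truth layout, so the epoch-scoring stage can be
  verified by round trip.
* :func:`simulate_feature_table` draws the per-participant period-averaged
  feature table directly (participant true means plus averaging noise), which
  is what the cohort-scale selection/confounding/PDP experiments consume.

Diurnal layout of a simulated day: nocturnal sleep is one contiguous
motionless block inside the 18:00-5:59 window with optional inserted wake
bouts; daytime naps are motionless blocks between 6:00 and 17:59; steps and
conversation occur in daytime wake minutes. A movement magnitude of exactly 0
encodes "no movement".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from .config import (
    GENERATED_FEATURES,
    CohortConfig,
    ConfigurationError,
    confounder_centers,
    confounder_sds,
)

__all__ = [
    "TrueParticipantState",
    "SimulatedCohort",
    "generate_participants",
    "generate_epoch_streams",
    "generate_mmse",
    "simulate_cohort",
    "simulate_feature_table",
]

#: Minutes per day / per half-window.
DAY_MINUTES = 1440
WINDOW_MINUTES = 720  # 18:00 -> 5:59
DAYTIME_START, DAYTIME_END = 360, 1080  # 6:00 -> 17:59 (end exclusive)
WINDOW_START = 1080  # 18:00

#: Calendar anchor and spacing of measurement cycles ("every 3 months").
START_DATE = _date(2016, 1, 4)
CYCLE_GAP_DAYS = 91

#: Mean length of a long (>=20 min) nocturnal wake bout, used to convert a
#: participant's WASO mean into a daily awakening probability.
_LONG_BOUT_MEAN = 44.0


@dataclass
class TrueParticipantState:
    """Ground truth for one simulated participant."""

    participant_id: str
    demographics: dict[str, float]
    true_daily_means: dict[str, float]
    true_mmse_expectation: float | None = None
    mmse: int | None = None


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulation run produced."""

    participants: pd.DataFrame
    epochs: pd.DataFrame
    truth: pd.DataFrame
    states: list[TrueParticipantState] = field(repr=False, default_factory=list)


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

def generate_participants(config: CohortConfig) -> list[TrueParticipantState]:
    """Draw participant demographics and true lifestyle daily means.

    Deterministic under a fixed ``config.seed``. Confounders shift the
    lifestyle means per ``config.confounding_strengths`` (e.g. older age
    lowers mean steps); the idiosyncratic between-person variance is reduced
    accordingly so each feature's marginal SD matches its configured value.
    """
    config.validate()
    n = config.n_participants
    if n == 0:
        return []
    rng = _rng(config, 0)
    demo = config.demographics

    age = rng.normal(demo["age_mean"], demo["age_sd"], n)
    gender = rng.binomial(1, demo["female_prob"], n).astype(float)
    education = np.clip(
        rng.normal(demo["education_mean"], demo["education_sd"], n),
        demo["education_min"],
        demo["education_max"],
    )
    bmi = np.clip(rng.normal(demo["bmi_mean"], demo["bmi_sd"], n), demo["bmi_min"], demo["bmi_max"])
    smoking = rng.choice(
        list(demo["smoking_probs"]), size=n, p=list(demo["smoking_probs"].values())
    ).astype(float)
    alcohol = rng.choice(
        list(demo["alcohol_probs"]), size=n, p=list(demo["alcohol_probs"].values())
    ).astype(float)
    hypertension = rng.binomial(1, demo["hypertension_prev"], n).astype(float)
    diabetes = rng.binomial(1, demo["diabetes_prev"], n).astype(float)
    hypercholesterolemia = rng.binomial(1, demo["hypercholesterolemia_prev"], n).astype(float)

    covariates = {
        "age": age,
        "gender": gender,
        "education": education,
        "bmi": bmi,
        "smoking": smoking,
        "alcohol": alcohol,
        "hypertension": hypertension,
        "diabetes": diabetes,
        "hypercholesterolemia": hypercholesterolemia,
    }

    centers = confounder_centers(demo)
    sds = confounder_sds(demo)

    means: dict[str, np.ndarray] = {}
    for feat in GENERATED_FEATURES:
        spec = config.features[feat]
        conf_part = np.zeros(n)
        conf_var = 0.0
        for conf, strengths in config.confounding_strengths.items():
            beta = strengths.get(feat, 0.0)
            if beta == 0.0:
                continue
            if conf not in covariates:
                raise ConfigurationError(f"confounding_strengths: unknown confounder {conf!r}")
            conf_part += beta * (covariates[conf] - centers[conf])
            conf_var += (beta * sds[conf]) ** 2
        resid_var = spec.sd**2 - conf_var
        if resid_var < 0:
            raise ConfigurationError(
                f"features[{feat!r}]: confounding contributes more variance "
                f"({math.sqrt(conf_var):.1f}) than the configured SD ({spec.sd})"
            )
        draw = spec.mean + conf_part + rng.normal(0.0, math.sqrt(resid_var), n)
        means[feat] = np.clip(draw, spec.minimum, spec.maximum)

    # TST mean must fit the 18:00-5:59 window.
    means["tst"] = np.minimum(means["tst"], float(WINDOW_MINUTES - 1))

    width = max(4, len(str(n)))
    states = []
    for i in range(n):
        states.append(
            TrueParticipantState(
                participant_id=f"P{i:0{width}d}",
                demographics={k: float(v[i]) for k, v in covariates.items()},
                true_daily_means={k: float(v[i]) for k, v in means.items()},
            )
        )
    return states


# ---------------------------------------------------------------------------
# outcome
# ---------------------------------------------------------------------------

def _effect_contributions(state: TrueParticipantState, config: CohortConfig) -> float:
    total = 0.0
    for eff in config.effect_specs:
        if eff.variable not in state.true_daily_means:
            raise ConfigurationError(f"effect_specs: unknown variable {eff.variable!r}")
        x = state.true_daily_means[eff.variable]
        spec = config.features[eff.variable]
        if eff.shape == "linear":
            total += eff.strength * (x - spec.mean) / spec.sd
        else:  # inverted_u
            z = (x - eff.peak_location) / eff.peak_width
            total += eff.strength * math.exp(-0.5 * z * z)
    return total


def generate_mmse(states: list[TrueParticipantState], config: CohortConfig) -> dict[str, int]:
    """Assemble integer MMSE scores in [0, 30] from the ground-truth model.

    ``score = round(base + linear + inverted-U + confounder terms + noise)``,
    clipped to the scale. The noiseless expectation is stored on each state as
    ``true_mmse_expectation`` before rounding/clipping.
    """
    if not states:
        return {}
    rng = _rng(config, 1)
    centers = confounder_centers(config.demographics)
    out: dict[str, int] = {}
    for state in states:
        expectation = config.mmse_base + _effect_contributions(state, config)
        for conf, strengths in config.confounding_strengths.items():
            beta = strengths.get("mmse", 0.0)
            if beta:
                expectation += beta * (state.demographics[conf] - centers[conf])
        state.true_mmse_expectation = expectation
        score = expectation + rng.normal(0.0, config.noise_sd)
        score = int(np.clip(round(score), 0, 30))
        state.mmse = score
        out[state.participant_id] = score
    return out


# ---------------------------------------------------------------------------
# epoch streams
# ---------------------------------------------------------------------------

def _place_blocks(
    rng: np.random.Generator, lo: int, hi: int, lengths: list[int], gap: int
) -> list[tuple[int, int]]:
    """Place blocks of given lengths in [lo, hi) with >= ``gap`` between them.

    Drops blocks (shortest first) if the span cannot host them. Returns
    ``(start, length)`` pairs in increasing start order.
    """
    lengths = sorted(lengths, reverse=True)
    while lengths:
        need = sum(lengths) + gap * (len(lengths) - 1)
        free = (hi - lo) - need
        if free >= 0:
            break
        lengths.pop()  # drop the shortest
    if not lengths:
        return []
    k = len(lengths)
    lens = [lengths[j] for j in rng.permutation(k)]
    cuts = np.sort(rng.integers(0, free + 1, size=k))
    blocks = []
    for i in range(k):
        start = lo + int(cuts[i]) + sum(lens[:i]) + gap * i
        blocks.append((start, lens[i]))
    return blocks


def generate_epoch_streams(
    state: TrueParticipantState, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate minute epochs and the per-day ground truth for one participant.

    Each scheduled day yields 1440 epochs; every cycle additionally emits the
    following morning (minutes 0-359) so the last evening's sleep window is
    complete. Conversation minutes carry >= 5 sound frames and all other
    minutes <= 4; sleep/nap minutes have movement exactly 0.

    Returns ``(epochs, truth)`` where ``truth`` has one row per scheduled day
    with the constructed sleep/nap/conversation/step totals.
    """
    config.validate()
    idx = int(state.participant_id.lstrip("P"))
    rng = _rng(config, 2, idx)
    means = state.true_daily_means
    feats = config.features

    epoch_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []

    for cycle in range(config.cycles):
        nd = config.days_per_cycle
        total = nd * DAY_MINUTES + WINDOW_MINUTES // 2  # + trailing morning
        movement = np.round(rng.uniform(5.0, 60.0, total), 1)
        pulses = np.maximum(
            np.rint(rng.normal(means["heart_rate"] + 2.0, 3.0, total)), 40
        ).astype(int)
        frames = rng.integers(0, 5, total)
        steps = np.zeros(total, dtype=int)
        cycle_start = START_DATE + timedelta(days=cycle * CYCLE_GAP_DAYS)

        for day in range(nd):
            base = day * DAY_MINUTES
            w0 = base + WINDOW_START  # window coordinate origin (18:00)

            # --- nocturnal sleep -----------------------------------------
            tst_day = int(
                np.clip(round(rng.normal(means["tst"], feats["tst"].daily_sd)), 180, 600)
            )
            p_long = min(means["waso"] / _LONG_BOUT_MEAN, 1.0)
            bout_lens: list[int] = []
            if rng.random() < p_long:
                bout_lens.append(int(rng.integers(20, 36)))
            lam_short = max(means["waso"] - p_long * 27.5, 0.0) / 7.5
            bout_lens += [int(rng.integers(3, 13)) for _ in range(rng.poisson(lam_short))]

            onset_w = int(np.clip(round(rng.normal(270, 40)), 40, 420))
            waso_day = sum(bout_lens)
            end_w = min(onset_w + tst_day + waso_day, WINDOW_MINUTES - 1)
            # ensure the block can host the bouts with 20-min sleep runs around
            while bout_lens and (end_w - onset_w) - sum(bout_lens) < 20 * (len(bout_lens) + 1):
                bout_lens.pop()
            bouts = _place_blocks(rng, onset_w + 20, end_w - 20, bout_lens, gap=20)
            waso_day = sum(ln for _, ln in bouts)
            tst_day = (end_w - onset_w) - waso_day

            sleep = np.ones(end_w - onset_w + 1, dtype=bool)
            for s, ln in bouts:
                sleep[s - onset_w : s - onset_w + ln] = False
            sl = slice(w0 + onset_w, w0 + end_w + 1)
            seg_move = movement[sl].copy()
            seg_move[sleep] = 0.0
            movement[sl] = seg_move
            seg_frames = frames[sl].copy()
            seg_frames[sleep] = 0
            frames[sl] = seg_frames
            seg_pulse = pulses[sl].copy()
            seg_pulse[sleep] = np.maximum(
                np.rint(rng.normal(means["heart_rate"] - 8.0, 2.0, int(sleep.sum()))), 40
            ).astype(int)
            pulses[sl] = seg_pulse

            # --- daytime naps --------------------------------------------
            nap_day = int(max(round(rng.normal(means["nap_time"], feats["nap_time"].daily_sd)), 0))
            if nap_day < 20:
                nap_day = 0
            nap_lens = []
            if nap_day >= 80:
                nap_lens = [nap_day // 2, nap_day - nap_day // 2]
            elif nap_day:
                nap_lens = [nap_day]
            naps = _place_blocks(rng, base + DAYTIME_START + 20, base + DAYTIME_END - 30, nap_lens, gap=10)
            nap_day = sum(ln for _, ln in naps)
            nap_mask = np.zeros(total, dtype=bool)
            for s, ln in naps:
                movement[s : s + ln] = 0.0
                frames[s : s + ln] = 0
                nap_mask[s : s + ln] = True

            # --- conversation and steps in daytime wake minutes ----------
            daytime = np.arange(base + DAYTIME_START, base + DAYTIME_END)
            wake_daytime = daytime[~nap_mask[daytime]]
            conv_day = int(
                np.clip(
                    round(rng.normal(means["conversation_time"], feats["conversation_time"].daily_sd)),
                    0,
                    len(wake_daytime),
                )
            )
            talk_idx = rng.choice(wake_daytime, size=conv_day, replace=False)
            frames[talk_idx] = 5 + rng.poisson(4.0, conv_day)

            steps_day = int(max(round(rng.normal(means["walking_steps"], feats["walking_steps"].daily_sd)), 0))
            alloc = rng.multinomial(steps_day, np.full(len(wake_daytime), 1.0 / len(wake_daytime)))
            steps[wake_daytime] += alloc

            # --- optional non-wear block ---------------------------------
            nonwear = False
            if config.nonwear_prob and rng.random() < config.nonwear_prob:
                nw0 = int(rng.integers(base + DAYTIME_START, base + DAYTIME_END - config.nonwear_minutes))
                pulses[nw0 : nw0 + config.nonwear_minutes] = 0
                nonwear = True

            day_date = cycle_start + timedelta(days=day)
            truth_rows.append(
                {
                    "participant_id": state.participant_id,
                    "date": pd.Timestamp(day_date),
                    "sleep_onset_min": onset_w,
                    "sleep_end_min": end_w,
                    "tst_min": tst_day,
                    "waso_min": waso_day,
                    "awakening_count": sum(1 for _, ln in bouts if ln >= 20),
                    "nap_min": nap_day,
                    "conversation_min": conv_day,
                    "steps": steps_day,
                    "nonwear": nonwear,
                }
            )

        # truth heart rate per day needs the final pulse arrays
        for day in range(nd):
            day_sl = slice(day * DAY_MINUTES, (day + 1) * DAY_MINUTES)
            truth_rows[-nd + day]["heart_rate"] = float(np.mean(pulses[day_sl]))

        minutes = np.arange(total)
        dates = [
            pd.Timestamp(cycle_start + timedelta(days=int(m // DAY_MINUTES))) for m in minutes
        ]
        epoch_frames.append(
            pd.DataFrame(
                {
                    "participant_id": state.participant_id,
                    "date": dates,
                    "minute_of_day": minutes % DAY_MINUTES,
                    "movement": movement,
                    "steps": steps,
                    "sound_frames": frames,
                    "pulses": pulses,
                }
            )
        )

    epochs = pd.concat(epoch_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return epochs, truth


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate the full cohort: participants, epoch streams, ground truth."""
    states = generate_participants(config)
    generate_mmse(states, config)
    epoch_parts, truth_parts = [], []
    for state in states:
        e, t = generate_epoch_streams(state, config)
        epoch_parts.append(e)
        truth_parts.append(t)
    participants = participants_frame(states)
    epochs = pd.concat(epoch_parts, ignore_index=True) if epoch_parts else pd.DataFrame()
    truth = pd.concat(truth_parts, ignore_index=True) if truth_parts else pd.DataFrame()
    return SimulatedCohort(participants=participants, epochs=epochs, truth=truth, states=states)


def participants_frame(states: list[TrueParticipantState]) -> pd.DataFrame:
    """Participant table (demographics, comorbidities, MMSE) as a DataFrame."""
    rows = []
    for s in states:
        row = {"participant_id": s.participant_id, **s.demographics}
        row["mmse"] = s.mmse
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature-level fast path
# ---------------------------------------------------------------------------

def simulate_feature_table(config: CohortConfig) -> tuple[pd.DataFrame, list[TrueParticipantState]]:
    """Draw the per-participant averaged feature table directly.

    Observed features are the participant's true daily mean plus averaging
    noise ``N(0, daily_sd / sqrt(n_days))`` — what scoring-then-averaging the
    epoch streams converges to. Sleep efficiency and awakening count are
    derived from the TST/WASO structure the epoch generator uses. Returns the
    unfiltered table (eligibility is applied downstream) and the ground-truth
    states.
    """
    states = generate_participants(config)
    generate_mmse(states, config)
    if not states:
        return pd.DataFrame(), states
    rng = _rng(config, 3)
    n = len(states)
    n_days = config.n_days
    table = participants_frame(states)

    for feat in GENERATED_FEATURES:
        spec = config.features[feat]
        true = np.array([s.true_daily_means[feat] for s in states])
        obs = true + rng.normal(0.0, spec.daily_sd / math.sqrt(n_days), n)
        table[feat] = np.clip(obs, spec.minimum, spec.maximum)

    # Derived sleep-structure features.
    p_long = np.clip(table["waso"].to_numpy() / _LONG_BOUT_MEAN, 0.0, 1.0)
    table["awakening_count"] = rng.binomial(n_days, p_long) / n_days
    table["sleep_efficiency"] = table["tst"] / (table["tst"] + table["waso"])
    return table, states
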