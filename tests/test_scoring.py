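"""Epoch scoring: wear detection, sleep, naps, conversation, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cogsense as cs
from cogsense.scoring import ScoringParams, _runs
from conftest import make_day

PARAMS = ScoringParams()


# --- wear detection -------------------------------------------------------

def test_all_pulses_positive_all_worn():
    worn = cs.detect_wear(np.ones(1440))
    assert worn.all() and worn.sum() == 1440


def test_single_long_zero_run_removed():
    pulses = np.ones(1440)
    pulses[600:720] = 0
    worn = cs.detect_wear(pulses, nonwear_run_min=60)
    assert worn.sum() == 1320
    assert not worn[600:720].any()


def test_short_zero_runs_stay_worn():
    pulses = np.ones(1440)
    pulses[100:130] = 0  # 30 < 60
    assert cs.detect_wear(pulses).all()


@pytest.mark.parametrize("seed", range(5))
def test_wear_mask_equals_run_length_oracle(seed):
    rng = np.random.default_rng(seed)
    pulses = rng.choice([0, 70], size=500, p=[0.3, 0.7])
    worn = cs.detect_wear(pulses, nonwear_run_min=10)
    # brute-force oracle: scan every index's surrounding zero run
    oracle = np.ones(500, dtype=bool)
    i = 0
    while i < 500:
        if pulses[i] == 0:
            j = i
            while j < 500 and pulses[j] == 0:
                j += 1
            if j - i >= 10:
                oracle[i:j] = False
            i = j
        else:
            i += 1
    assert np.array_equal(worn, oracle)


# --- sleep ----------------------------------------------------------------

def _window(motionless_spans, moving_value=30.0):
    move = np.full(720, moving_value)
    for a, b in motionless_spans:
        move[a : b + 1] = 0.0
    return move


def test_uninterrupted_sleep_2300_to_0559():
    move = _window([(300, 719)])
    s = cs.score_sleep(move, np.ones(720, bool))
    assert (s.sleep_onset, s.sleep_end) == (300, 719)
    assert s.waso == 0 and s.tst == 419 and s.efficiency == 1.0 and s.awakening_count == 0


def test_single_30min_awakening():
    # movement bout 02:00-02:29 inside a 23:00-05:59 sleep block
    move = _window([(300, 719)])
    move[480:510] = 30.0
    s = cs.score_sleep(move, np.ones(720, bool))
    assert s.awakening_count == 1 and s.waso == 30
    assert s.tst == (719 - 300) - 30
    assert s.efficiency == pytest.approx(389 / 419)


def test_all_moving_scores_no_sleep():
    s = cs.score_sleep(np.full(720, 30.0), np.ones(720, bool))
    assert s.sleep_onset is None and s.tst == 0 and s.efficiency is None


def test_short_blocks_do_not_qualify():
    move = _window([(100, 118)])  # 19 min < 20
    s = cs.score_sleep(move, np.ones(720, bool))
    assert s.sleep_onset is None


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 700), st.integers(1, 100)), min_size=0, max_size=6))
def test_sleep_identities_hold_for_arbitrary_layouts(spans):
    move = np.full(720, 30.0)
    for start, length in spans:
        move[start : min(start + length, 720)] = 0.0
    s = cs.score_sleep(move, np.ones(720, bool))
    if s.sleep_onset is None:
        assert s.tst == 0 and s.waso == 0 and s.awakening_count == 0
    else:
        assert s.tst + s.waso == s.sleep_end - s.sleep_onset
        if s.sleep_end > s.sleep_onset:
            assert 0 < s.efficiency <= 1.0
            assert (s.efficiency == 1.0) == (s.waso == 0)


# --- naps and conversation ------------------------------------------------

def test_no_motionless_daytime_is_zero_nap():
    assert cs.score_nap(np.full(720, 30.0), np.ones(720, bool)) == 0


def test_single_45min_nap():
    move = np.full(720, 30.0)
    move[100:145] = 0.0
    assert cs.score_nap(move, np.ones(720, bool)) == 45


@pytest.mark.parametrize("seed", range(5))
def test_nap_equals_run_length_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    move = rng.choice([0.0, 30.0], size=720, p=[0.4, 0.6])
    got = cs.score_nap(move, np.ones(720, bool), ScoringParams(nap_block_min=15))
    starts, lengths = _runs(move == 0.0)
    assert got == lengths[lengths >= 15].sum()


def test_conversation_boundary_at_threshold():
    frames = np.full(1440, 4)
    worn = np.ones(1440, bool)
    assert cs.score_conversation(frames, worn) == 0  # "more than four" excludes 4
    frames[:30] = 5
    assert cs.score_conversation(frames, worn) == 30
    # inclusive reading is configurable
    assert cs.score_conversation(frames, worn, ScoringParams(conversation_min_frames=4)) == 1440


@pytest.mark.parametrize("seed", range(3))
def test_conversation_equals_predicate_count(seed):
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 10, 1440)
    worn = rng.random(1440) > 0.1
    got = cs.score_conversation(frames, worn)
    assert got == int(np.sum(worn & (frames >= 5)))


# --- daily summary and cohort scoring ------------------------------------

def test_constant_pulses_mean_heart_rate():
    day = make_day(pulses_value=64, steps_total=0)
    daily = cs.score_cohort(day)
    assert len(daily) == 1
    assert daily.iloc[0]["heart_rate"] == 64.0
    assert daily.iloc[0]["steps"] == 0.0


def test_summarized_day_matches_spreadsheet_recomputation():
    day = make_day(
        sleep=(280, 700),
        wake_bouts=[(400, 25)],
        naps=[(500, 40)],
        conversation=[(600, 90)],
        steps_total=4200,
    )
    rec = cs.score_cohort(day).iloc[0]
    assert rec["tst"] == (700 - 280) - 25 and rec["waso"] == 25
    assert rec["awakening_count"] == 1
    assert rec["nap_min"] == 40 and rec["conversation_min"] == 90
    assert rec["steps"] == 4200
    assert rec["valid"]


def test_scoring_invariant_to_epoch_row_order(small_cohort):
    daily_sorted = cs.score_cohort(small_cohort.epochs)
    shuffled = small_cohort.epochs.sample(frac=1.0, random_state=1).reset_index(drop=True)
    daily_shuffled = cs.score_cohort(shuffled)
    pd.testing.assert_frame_equal(
        daily_sorted.reset_index(drop=True), daily_shuffled.reset_index(drop=True)
    )


def test_missing_morning_flags_incomplete_window():
    day = make_day()
    day = day[day["date"] == day["date"].iloc[0]]  # drop the next morning
    rec = cs.score_cohort(day).iloc[0]
    assert not rec["sleep_complete"] and not rec["valid"]


def test_removing_worn_minutes_never_increases_activity_counts():
    day = make_day(conversation=[(600, 90)], steps_total=3000)
    full = cs.score_cohort(day).iloc[0]
    day_masked = day.copy()
    # remove a 2-hour block (pulse 0 run >= 60 -> not worn)
    mask = (day_masked["minute_of_day"].between(600, 719)) & (
        day_masked["date"] == day_masked["date"].iloc[0]
    )
    day_masked.loc[mask, "pulses"] = 0
    masked = cs.score_cohort(day_masked).iloc[0]
    assert masked["conversation_min"] <= full["conversation_min"]
    assert masked["steps"] <= full["steps"]
    assert masked["worn_minutes"] == full["worn_minutes"] - 120
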