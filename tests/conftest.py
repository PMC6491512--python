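import numpy as np
import pandas as pd
import pytest

import cogsense as cs


@pytest.fixture(scope="session")
def small_cohort():
    """A small epoch-level cohort with ground truth (shared, read-only)."""
    cfg = cs.CohortConfig(n_participants=6, days_per_cycle=4, cycles=1, seed=42)
    return cs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_daily(small_cohort):
    return cs.score_cohort(small_cohort.epochs)


@pytest.fixture(scope="session")
def feature_table():
    """A mid-sized feature-level cohort table (eligible rows only)."""
    cfg = cs.CohortConfig(n_participants=500, seed=7)
    table, _ = cs.simulate_feature_table(cfg)
    return cs.eligible_table(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_day(
    sleep=(300, 719),
    wake_bouts=(),
    naps=(),
    conversation=(),
    steps_total=0,
    pulses_value=64,
):
    """Construct one participant-day (plus next morning) of epochs by hand.

    ``sleep`` is (onset, end) in window minutes from 18:00; ``wake_bouts``
    and ``naps`` are (start, length) in window / absolute day minutes.
    Returns a DataFrame in the epoch-CSV dialect for dates d and d+1 (the
    morning completing the window).
    """
    total = 1440 + 360
    movement = np.full(total, 30.0)
    frames = np.zeros(total, dtype=int)
    pulses = np.full(total, pulses_value, dtype=int)
    steps = np.zeros(total, dtype=int)

    onset, end = sleep
    if onset is not None:
        movement[1080 + onset : 1080 + end + 1] = 0.0
    for start, length in wake_bouts:
        movement[1080 + start : 1080 + start + length] = 30.0
    for start, length in naps:
        movement[start : start + length] = 0.0
    for start, length in conversation:
        frames[start : start + length] = 6
    if steps_total:
        day_wake = np.flatnonzero(movement[360:1080] > 0) + 360
        alloc = np.random.default_rng(0).multinomial(
            steps_total, np.full(len(day_wake), 1 / len(day_wake))
        )
        steps[day_wake] = alloc

    minutes = np.arange(total)
    d0 = pd.Timestamp("2020-03-02")
    return pd.DataFrame(
        {
            "participant_id": "X0001",
            "date": [d0 + pd.Timedelta(days=int(m // 1440)) for m in minutes],
            "minute_of_day": minutes % 1440,
            "movement": movement,
            "steps": steps,
            "sound_frames": frames,
            "pulses": pulses,
        }
    )
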