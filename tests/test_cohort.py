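"""Eligibility rules, feature averaging, and detection-validation metrics."""

import numpy as np
import pandas as pd
import pytest

import cogsense as cs


def _participants(rows):
    cols = ["participant_id", "age", "mmse"]
    df = pd.DataFrame(rows, columns=cols)
    return df


class TestEligibility:
    def test_age_boundary_excluded_with_reason(self):
        out = cs.apply_eligibility(_participants([("a", 64.0, 28), ("b", 65.0, 28)]))
        assert not out.loc[out.participant_id == "a", "eligible"].item()
        assert out.loc[out.participant_id == "a", "exclusion_reasons"].item() == "age"
        assert out.loc[out.participant_id == "b", "eligible"].item()

    def test_mmse_20_is_retained(self):
        out = cs.apply_eligibility(_participants([("a", 70.0, 20), ("b", 70.0, 19)]))
        assert out.loc[out.participant_id == "a", "eligible"].item()
        assert out.loc[out.participant_id == "b", "exclusion_reasons"].item() == "mmse"

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cs.apply_eligibility(_participants([("a", 70.0, 25), ("a", 71.0, 25)]))

    def test_surviving_set_equals_brute_force_filter(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(n)],
                "age": rng.uniform(55, 95, n),
                "mmse": rng.integers(10, 31, n),
            }
        )
        out = cs.apply_eligibility(df)
        expected = (df["age"] >= 65) & (df["mmse"] >= 20)
        assert np.array_equal(out["eligible"].to_numpy(), expected.to_numpy())

    def test_filtering_is_idempotent(self, rng):
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(50)],
                "age": rng.uniform(55, 95, 50),
                "mmse": rng.integers(10, 31, 50),
            }
        )
        once = cs.apply_eligibility(df)
        twice = cs.apply_eligibility(once.drop(columns=["eligible", "exclusion_reasons"]))
        assert (once["eligible"] == twice["eligible"]).all()

    def test_insufficient_valid_days(self):
        daily = pd.DataFrame(
            {
                "participant_id": ["a"] * 10 + ["b"] * 3,
                "valid": [True] * 13,
            }
        )
        out = cs.apply_eligibility(
            _participants([("a", 70.0, 25), ("b", 70.0, 25)]), daily, min_valid_days=7
        )
        assert out.loc[out.participant_id == "b", "exclusion_reasons"].item() == "insufficient_days"


class TestAveraging:
    def _daily(self, steps_by_day):
        n = len(steps_by_day)
        return pd.DataFrame(
            {
                "participant_id": ["a"] * n,
                "steps": steps_by_day,
                "conversation_min": [100.0] * n,
                "heart_rate": [60.0] * n,
                "tst": [400.0] * n,
                "waso": [20.0] * n,
                "efficiency": [0.95] * n,
                "awakening_count": [1.0] * n,
                "nap_min": [30.0] * n,
                "valid": [True] * n,
            }
        )

    def test_single_day_identity(self):
        out = cs.average_features(self._daily([4000.0]))
        assert out.iloc[0]["walking_steps"] == 4000.0 and out.iloc[0]["n_valid_days"] == 1

    def test_two_day_mean(self):
        out = cs.average_features(self._daily([4000.0, 6000.0]))
        assert out.iloc[0]["walking_steps"] == 5000.0

    def test_commutes_with_day_reordering(self, rng):
        daily = self._daily(list(rng.uniform(2000, 9000, 8)))
        a = cs.average_features(daily)
        b = cs.average_features(daily.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_days_ignored(self):
        daily = self._daily([4000.0, 6000.0])
        daily.loc[1, "valid"] = False
        assert cs.average_features(daily).iloc[0]["walking_steps"] == 4000.0


def test_bmi_formula():
    assert cs.compute_bmi(60.0, 1.6) == pytest.approx(23.4375)
    assert cs.compute_bmi(0.0, 1.7) == 0.0
    with pytest.raises(ValueError):
        cs.compute_bmi(60.0, 0.0)


@pytest.mark.parametrize("w,h", [(55, 1.5), (80, 1.83), (70.5, 1.62)])
def test_bmi_matches_direct_formula(w, h):
    assert cs.compute_bmi(w, h) == w / h**2


class TestDetectionMetrics:
    def test_f_measure_of_reported_precision_recall(self):
        assert cs.f_measure(0.698, 0.774) == pytest.approx(0.734, abs=5e-4)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 1, 0, 1])
        m = cs.detection_metrics(truth, truth)
        assert m["precision"] == m["recall"] == m["f_measure"] == 1.0

    def test_no_positive_predictions_flagged_nan(self):
        m = cs.detection_metrics(np.zeros(10), np.ones(10))
        assert np.isnan(m["precision"]) and m["recall"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random(300) > 0.5
        truth = rng.random(300) > 0.5
        m = cs.detection_metrics(pred, truth)
        tp = np.sum(pred & truth)
        fp = np.sum(pred & ~truth)
        fn = np.sum(~pred & truth)
        assert m["precision"] == tp / (tp + fp)
        assert m["recall"] == tp / (tp + fn)
        p, r = m["precision"], m["recall"]
        assert m["f_measure"] == pytest.approx(2 * p * r / (p + r))
        assert min(p, r) <= m["f_measure"] <= max(p, r)  # harmonic-mean bound

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cs.detection_metrics(np.ones(5), np.ones(6))


class TestFalseDetection:
    def test_zero_detections(self):
        assert cs.false_detection_rate(np.zeros(16)) == 0.0

    def test_sixteen_items_rate(self):
        detected = np.full(16, 72.0 / 16)
        assert cs.false_detection_rate(detected, minutes_per_item=100) == pytest.approx(0.045)

    def test_single_fully_detected_item(self):
        assert cs.false_detection_rate(np.array([100.0]), minutes_per_item=100) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cs.false_detection_rate(np.array([-1.0]))


class TestValidationCorrelation:
    def test_identical_sequences(self):
        x = np.array([1.0, 3.0, 7.0, 2.0])
        assert cs.validation_correlation(x, x)["r"] == pytest.approx(1.0)

    def test_reversed_linear_map(self):
        x = np.array([1.0, 3.0, 7.0, 2.0])
        assert cs.validation_correlation(x, -2 * x + 5)["r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        r = cs.validation_correlation(x, y)["r"]
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_flagged(self):
        out = cs.validation_correlation(np.ones(5), np.arange(5.0))
        assert out["undefined"] and np.isnan(out["r"])


def test_build_feature_table_end_to_end(small_cohort, small_daily):
    table, excluded = cs.build_feature_table(
        small_cohort.participants, small_daily, min_valid_days=2
    )
    assert set(cs.TABLE_COLUMNS + ["mmse", "participant_id"]) == set(table.columns)
    assert len(table) + len(excluded) == len(small_cohort.participants)
    assert table[cs.TABLE_COLUMNS + ["mmse"]].notna().all().all()
    # averaged lifestyle features agree with a hand recomputation
    pid = table["participant_id"].iloc[0]
    valid = small_daily[(small_daily.participant_id == pid) & small_daily.valid]
    assert table.loc[table.participant_id == pid, "walking_steps"].item() == pytest.approx(
        valid["steps"].mean()
    )
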