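import itertools
import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from shiftsleep import features
from tests.conftest import make_minutes_frame


def sampen_oracle(x, m, r):
    """Naive template-counting sample entropy (Richman-Moorman convention)."""
    x = list(x)
    n = len(x)
    nt = n - m

    def count(length):
        c = 0
        for i in range(nt):
            for j in range(nt):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return -math.log(a / b)


def segment_entropy_oracle(steps):
    runs = [(k, len(list(g))) for k, g in itertools.groupby(np.asarray(steps) > 0)]

    def ent(durations):
        if not durations:
            return 0.0
        out = 0.0
        for d in set(durations):
            p = durations.count(d) / len(durations)
            out -= p * math.log(p)
        return out

    return (
        ent([l for k, l in runs if k]),
        ent([l for k, l in runs if not k]),
    )


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert features.sample_entropy([5.0] * 100) == 0.0

    def test_alternating_series_matches_oracle(self):
        x = [1, 2, 1, 2, 1, 2, 1, 2]
        got = features.sample_entropy(x, m=2, r=0.5)
        expect = sampen_oracle(x, 2, 0.5)
        assert got == pytest.approx(expect)

    def test_too_short_is_missing(self):
        assert np.isnan(features.sample_entropy([1.0, 2.0, 3.0], m=2))

    def test_matches_oracle_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            x = np.round(rng.normal(0, 1, n), 3)
            m = int(rng.integers(1, 3))
            r = float(0.2 * x.std())
            if r == 0:
                continue
            got = features.sample_entropy(x, m=m, r=r)
            expect = sampen_oracle(x, m, r)
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-10)

    def test_nonnegative(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 50)
            v = features.sample_entropy(x)
            assert np.isnan(v) or v >= 0


class TestSegmentDurationEntropy:
    def test_all_zero_day(self):
        ent_step, ent_non = features.segment_duration_entropy(np.zeros(1440))
        assert ent_non == 0.0  # single stationary segment
        assert ent_step == 0.0  # absent class scores 0

    def test_durations_3_3_5(self):
        # active runs of 3, 3, 5 minutes
        steps = [1, 1, 1, 0, 1, 1, 1, 0, 0, 1, 1, 1, 1, 1]
        ent_step, _ = features.segment_duration_entropy(steps)
        expect = -(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3))
        assert ent_step == pytest.approx(expect)
        assert round(expect, 4) == 0.6365

    def test_equal_durations_zero(self):
        steps = [1, 1, 0, 0, 1, 1, 0, 0]
        ent_step, ent_non = features.segment_duration_entropy(steps)
        assert ent_step == 0.0
        assert ent_non == 0.0

    def test_missing_minutes_count_stationary(self):
        steps = [1.0, np.nan, 1.0]
        ent_step, ent_non = features.segment_duration_entropy(steps)
        # runs: active 1, stationary 1, active 1
        assert ent_step == 0.0
        assert ent_non == 0.0

    def test_empty_series_missing(self):
        ent_step, ent_non = features.segment_duration_entropy([])
        assert np.isnan(ent_step) and np.isnan(ent_non)

    def test_matches_oracle_on_random_series(self, rng):
        for _ in range(100):
            steps = (rng.random(int(rng.integers(5, 200))) < 0.3) * rng.integers(
                1, 50
            )
            got = features.segment_duration_entropy(steps)
            expect = segment_entropy_oracle(steps)
            assert got[0] == pytest.approx(expect[0])
            assert got[1] == pytest.approx(expect[1])


def minimal_tables(minutes=None, sleep=None, morning=None, evening=None):
    participants = pd.DataFrame([
        {"participant": "P1", "hospital": 1, "enroll_order": 1,
         "start_date": "2021-03-01", "study_days": 3},
    ])
    return {
        "participants": participants,
        "minutes": minutes if minutes is not None else make_minutes_frame().iloc[:0],
        "sleep_periods": sleep if sleep is not None else pd.DataFrame(
            columns=["participant", "start", "end", "duration_min", "efficiency"]
        ),
        "morning_survey": morning if morning is not None else pd.DataFrame(
            columns=["participant", "date", "main_sleep_start", "main_sleep_end"]
        ),
        "evening_survey": evening if evening is not None else pd.DataFrame(
            columns=["participant", "date", "work_bits"]
        ),
    }


class TestDailyFeatures:
    def test_main_sleep_is_longest_wearable(self):
        sleep = pd.DataFrame([
            {"participant": "P1", "start": "2021-03-01T01:00", "end": "2021-03-01T08:00",
             "duration_min": 420, "efficiency": 90.0},
            {"participant": "P1", "start": "2021-03-01T14:00", "end": "2021-03-01T15:30",
             "duration_min": 90, "efficiency": 85.0},
        ])
        daily = features.daily_features(minimal_tables(sleep=sleep))
        row = daily[daily["date"] == date(2021, 3, 1)].iloc[0]
        assert row["sleep_duration"] == 420.0
        assert row["sleep_efficiency"] == 90.0

    def test_caffeine_to_sleep(self):
        morning = pd.DataFrame([
            {"participant": "P1", "date": "2021-03-02",
             "main_sleep_start": "2021-03-01T23:00", "main_sleep_end": "2021-03-02T06:00",
             "caffeine_amount": 2, "caffeine_last_time": "2021-03-01T20:00"},
        ])
        daily = features.daily_features(minimal_tables(morning=morning))
        row = daily[daily["date"] == date(2021, 3, 2)].iloc[0]
        assert row["caffeine_to_sleep"] == 180.0

    def test_missing_evening_keeps_record(self):
        morning = pd.DataFrame([
            {"participant": "P1", "date": "2021-03-01",
             "main_sleep_start": "2021-03-01T00:00", "main_sleep_end": "2021-03-01T06:00",
             "brightness_sleep": 10},
        ])
        daily = features.daily_features(minimal_tables(morning=morning))
        row = daily[daily["date"] == date(2021, 3, 1)].iloc[0]
        assert row["brightness_sleep"] == 10.0
        assert np.isnan(row["stress"])
        assert np.isnan(row["work_today_total"])

    def test_hr_and_steps_stats(self):
        hr = np.full(1440, 70.0)
        steps = np.zeros(1440)
        steps[600:630] = 50
        minutes = make_minutes_frame(hr=hr, steps=steps)
        daily = features.daily_features(minimal_tables(minutes=minutes))
        row = daily[daily["date"] == date(2021, 3, 1)].iloc[0]
        assert row["hr_mean"] == 70.0
        assert row["hr_entropy"] == 0.0
        assert row["steps"] == 1500.0

    def test_purity(self, small_cohort):
        d1 = features.daily_features(small_cohort.tables)
        d2 = features.daily_features(small_cohort.tables)
        pd.testing.assert_frame_equal(d1, d2)


class TestAssembleAdviceSamples:
    def make_daily(self, values, participant="P1"):
        rows = []
        for i, v in enumerate(values):
            rec = {"participant": participant, "date": date(2021, 3, 1 + i)}
            for col in features.MODEL_FEATURES:
                rec[col] = v
            rows.append(rec)
        df = pd.DataFrame(rows)
        for col in features.ALL_DAILY_FEATURES:
            if col not in df.columns:
                df[col] = np.nan
        return df

    def test_window_mean_and_sd(self):
        daily = self.make_daily([1.0, 2.0, 3.0, 4.0])
        adv = pd.DataFrame([
            {"participant": "P1", "date": "2021-03-05", "message_ids": "20",
             "response": "none"},
        ])
        samples = features.assemble_advice_samples(daily, adv)
        assert len(samples) == 1
        assert samples.loc[0, "hr_mean__mean"] == 2.5
        assert samples.loc[0, "hr_mean__sd"] == pytest.approx(1.2909944, abs=1e-6)
        assert samples.loc[0, "label_20"] == 1
        assert samples.loc[0, "label_21"] == 0

    def test_missing_value_in_window_drops_sample(self):
        daily = self.make_daily([1.0, 2.0, 3.0, 4.0])
        daily.loc[1, "brightness_sleep"] = np.nan
        adv = pd.DataFrame([
            {"participant": "P1", "date": "2021-03-05", "message_ids": "20",
             "response": "none"},
        ])
        samples = features.assemble_advice_samples(daily, adv)
        assert len(samples) == 0

    def test_short_history_drops_sample(self):
        daily = self.make_daily([1.0, 2.0, 3.0])
        adv = pd.DataFrame([
            {"participant": "P1", "date": "2021-03-04", "message_ids": "20",
             "response": "none"},
        ])
        assert len(features.assemble_advice_samples(daily, adv)) == 0

    def test_response_features_track_history(self):
        daily = self.make_daily([1.0] * 10)
        adv = pd.DataFrame([
            {"participant": "P1", "date": "2021-03-05", "message_ids": "20|21",
             "response": "eager"},
            {"participant": "P1", "date": "2021-03-07", "message_ids": "4",
             "response": "difficult"},
            {"participant": "P1", "date": "2021-03-09", "message_ids": "20",
             "response": "none"},
        ])
        samples = features.assemble_advice_samples(daily, adv)
        # first event: no history anywhere
        assert samples.loc[0, "resp_20"] == 0
        # second event: saw eager response to a piece containing 20 and 21
        assert samples.loc[1, "resp_20"] == 1
        assert samples.loc[1, "resp_21"] == 1
        assert samples.loc[1, "resp_4"] == 0
        # third event: msg 4 was responded difficult
        assert samples.loc[2, "resp_4"] == -1

    def test_never_advised_response_zero(self):
        daily = self.make_daily([1.0] * 6)
        adv = pd.DataFrame([
            {"participant": "P1", "date": "2021-03-06", "message_ids": "7",
             "response": "none"},
        ])
        samples = features.assemble_advice_samples(daily, adv)
        assert samples.loc[0, "resp_20"] == 0
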