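import numpy as np
import pandas as pd
import pytest

from shiftsleep import features
from shiftsleep.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12-participant cohort with mild missingness, shared across tests."""
    cfg = CohortConfig(
        n_participants=12,
        study_days=35,
        seed=3,
        missingness={"morning": 0.05, "evening": 0.05, "fitbit": 0.03},
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_daily(small_cohort):
    return features.daily_features(small_cohort.tables)


@pytest.fixture(scope="session")
def small_samples(small_cohort, small_daily):
    return features.assemble_advice_samples(small_daily, small_cohort.advice)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_minutes_frame(participant="P1", date="2021-03-01", hr=None, steps=None):
    """One participant-day minutes frame (1440 rows) for feature tests."""
    ts = pd.date_range(f"{date} 00:00", periods=1440, freq="min")
    if hr is None:
        hr = np.full(1440, 70.0)
    if steps is None:
        steps = np.zeros(1440)
    return pd.DataFrame(
        {"participant": participant, "timestamp": ts, "heart_rate": hr, "steps": steps}
    )
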