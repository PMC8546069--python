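import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from grouplink.config import StudyConfig
from grouplink.synthetic import default_truth, generate_roster, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A compact study: 4 cohorts of 5, three 30-minute sessions."""
    return StudyConfig(
        n_cohorts=4,
        cohort_sizes=(5, 5, 5, 5),
        n_sessions=3,
        session_lengths_min=(30, 30, 30),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    roster = generate_roster(small_config)
    truth = default_truth(small_config, roster)
    return simulate_study(small_config, truth=truth, roster=roster)


@pytest.fixture()
def clean_beat_minute() -> pd.DataFrame:
    """One clean minute of constant 750 ms beats for one person."""
    ibi = 750.0
    times = np.arange(1, 81) * ibi / 1000.0
    return pd.DataFrame(
        {
            "person_id": "P001",
            "session": 1,
            "window": "session",
            "beat_time_s": times[times <= 60.0],
            "ibi_ms": ibi,
        }
    )
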