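import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mealtrace.records import ENTRY_COLUMNS
from mealtrace.synthetic import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_entries(rows: list[dict]) -> pd.DataFrame:
    """Build an entries frame from partial row dicts (sane defaults)."""
    defaults = {
        "participant_id": "P1",
        "day": 1,
        "time_min": 12 * 60,
        "meal": "lunch",
        "food_group": "meat",
        "weight_g": 100.0,
        "energy_kj": 500.0,
        "protein_g": 20.0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=ENTRY_COLUMNS)


def make_participants(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "participant_id": "P1",
        "sex": "male",
        "age_yr": 68.0,
        "height_m": 1.75,
        "weight_kg": 80.0,
        "education": "secondary",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-participant synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(n_participants=150, seed=20240917 % 2**31))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
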