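import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from afcea.params import demo_parameters
from afcea.synthetic import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def small_population():
    """A modest synthetic claims dataset shared across tests."""
    config = GeneratorConfig(n_patients=2_000, seed=42)
    return generate_population(config), config


@pytest.fixture(scope="session")
def demo_mp():
    return demo_parameters()


def make_visits(rows):
    """Visit-table helper: rows of (pid, date, code, setting[, imaging])."""
    records = []
    for row in rows:
        pid, date, code, setting = row[:4]
        imaging = row[4] if len(row) > 4 else False
        records.append(
            {
                "patient_id": pid,
                "date": pd.Timestamp(date),
                "icd10_code": code,
                "setting": setting,
                "brain_imaging_flag": imaging,
            }
        )
    return pd.DataFrame(records)


def make_patients(rows):
    """Patient-table helper: rows of (pid, sex, birth[, death])."""
    records = []
    for row in rows:
        pid, sex, birth = row[:3]
        death = row[3] if len(row) > 3 else None
        records.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": pd.Timestamp(birth),
                "death_date": pd.Timestamp(death) if death else pd.NaT,
            }
        )
    return pd.DataFrame(records)
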