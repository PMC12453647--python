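import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sepsisnet.cohort import Cohort, FeatureSchema, PatientRecord
from sepsisnet.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_schema() -> FeatureSchema:
    return FeatureSchema(
        feature_names=("HR", "Temp", "WBC", "Gender"),
        groups={"HR": "vital", "Temp": "vital", "WBC": "lab", "Gender": "demographic"},
        categorical={"Gender": ("Male", "Female", "Other")},
    )


@pytest.fixture
def tiny_cohort(tiny_schema) -> Cohort:
    """Two hand-built patients; patient B becomes septic at hour 2."""
    a = PatientRecord(
        patient_id="A",
        times=[0, 1, 2],
        values=[[80, 36.5, 7.0, 0], [82, 0.0, 0.0, 0], [85, 36.9, 0.0, 0]],
        observed_mask=[
            [True, True, True, True],
            [True, False, False, True],
            [True, True, False, True],
        ],
        labels=[0, 0, 0],
    )
    b = PatientRecord(
        patient_id="B",
        times=[0, 1, 2, 3],
        values=[[95, 37.0, 9.0, 1], [100, 37.5, 0.0, 1], [110, 38.2, 14.0, 1],
                [115, 38.5, 0.0, 1]],
        observed_mask=[
            [True, True, True, True],
            [True, True, False, True],
            [True, True, True, True],
            [True, True, False, True],
        ],
        labels=[0, 0, 1, 1],
    )
    return Cohort(tiny_schema, [a, b])


@pytest.fixture(scope="session")
def small_sim_cohort() -> Cohort:
    """A 200-patient synthetic cohort shared across tests."""
    return simulate_cohort(SimConfig(n_patients=200, seed=7))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
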