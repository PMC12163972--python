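import pytest
from hypothesis import settings

from tbvtools import PatientRecord, RunConfig, Sex, profile_for

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")
from tbvtools.estimators import estimate_all


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture
def male_patient():
    """A severely obese man matching the standardized worked example."""
    return PatientRecord(id="HYP", sex=Sex.MALE, height_cm=173.0,
                         weight_kg=120.0, hematocrit=0.40)


@pytest.fixture
def small_cohort():
    """Six patients spanning both sexes and severity classes."""
    return [
        PatientRecord(id="F1", sex=Sex.FEMALE, height_cm=160.0, weight_kg=80.0),
        PatientRecord(id="F2", sex=Sex.FEMALE, height_cm=165.0, weight_kg=95.0),
        PatientRecord(id="F3", sex=Sex.FEMALE, height_cm=158.0, weight_kg=100.0),
        PatientRecord(id="M1", sex=Sex.MALE, height_cm=175.0, weight_kg=100.0),
        PatientRecord(id="M2", sex=Sex.MALE, height_cm=180.0, weight_kg=125.0),
        PatientRecord(id="M3", sex=Sex.MALE, height_cm=170.0, weight_kg=110.0),
    ]


@pytest.fixture
def small_estimate_sets(small_cohort, run_config):
    return [
        estimate_all(rec, profile_for(rec), run_config.formulas)
        for rec in small_cohort
    ]
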