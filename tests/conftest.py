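import pytest

from matews.cohort import DayObservation, PatientRecord
from matews.scores import load_score_definitions, score_cohort
from matews.synthetic import generate_cohort

#: Textbook-normal adult observation values; used by several suites.
NORMAL_VALUES = dict(
    systolic_bp=120.0,
    diastolic_bp=80.0,
    heart_rate=70.0,
    respiratory_rate=14.0,
    temperature=36.8,
    spo2=98.0,
    gcs=15,
    avpu="alert",
    wbc=8.0,
    lactate=1.0,
    paco2=40.0,
    urine_output=60.0,
    mental_state_altered=False,
)


def make_obs(day_index=0, **overrides) -> DayObservation:
    values = {**NORMAL_VALUES, **overrides}
    return DayObservation(day_index=day_index, **values)


def make_record(
    woman_id="W1", pregnancy_status="pregnant", days=(0,), obs_overrides=None, **rec_kwargs
) -> PatientRecord:
    rec = PatientRecord(id=woman_id, pregnancy_status=pregnancy_status, **rec_kwargs)
    for d in days:
        rec.add_observation(make_obs(day_index=d, **(obs_overrides or {})))
    return rec


@pytest.fixture(scope="session")
def registry():
    return load_score_definitions()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: n = 2560, published severity mix."""
    return generate_cohort(seed=17)


@pytest.fixture(scope="session")
def default_matrix(registry, default_cohort):
    return score_cohort(registry, default_cohort)
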