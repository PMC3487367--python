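import pytest

from scampqi.cohort import DeviationCategory, Encounter, Era, Sex
from scampqi.synth import canonical_cohorts


def make_encounter(**overrides) -> Encounter:
    """A minimal valid encounter; override any field."""
    base = dict(
        patient_id="p-0001",
        era=Era.SCAMP,
        sex=Sex.FEMALE,
        age_years=13.0,
        exertional_pain=False,
        palpitations=False,
        positive_pmh=False,
        positive_fh=False,
        abnormal_exam=False,
        abnormal_ecg=False,
        echo_done=False,
        est_done=False,
        holter_done=False,
        event_monitor_done=False,
        provider_id="prov-01",
        deviation_reason=None,
    )
    base.update(overrides)
    return Encounter(**base)


@pytest.fixture(scope="session")
def canonical_pair():
    return canonical_cohorts()


@pytest.fixture(scope="session")
def historical_cohort(canonical_pair):
    return canonical_pair[0]


@pytest.fixture(scope="session")
def scamp_cohort(canonical_pair):
    return canonical_pair[1]
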