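import pytest

from plsd.cohort import CancerEvent, PatientRecord
from plsd.simulate import SimulationConfig, simulate_cohort, simulate_survival_after_cancer


def make_record(
    id="p1",
    series="finnish",
    sex="female",
    age_inclusion=30.0,
    year_inclusion=2000,
    age_last_observation=40.0,
    age_death=None,
    events=(),
    months=None,
):
    return PatientRecord(
        id=id,
        series=series,
        sex=sex,
        age_inclusion=age_inclusion,
        year_inclusion=year_inclusion,
        age_last_observation=age_last_observation,
        age_death=age_death,
        events=tuple(
            CancerEvent(age_at_diagnosis=a, icd9=c) if not isinstance(a, CancerEvent) else a
            for a, c in events
        ),
        months_colonoscopy_to_crc=months,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Hand-built two-series cohort exercising both cancer classes."""
    return [
        make_record(id="f1", series="finnish", sex="male", age_inclusion=28.0,
                    age_last_observation=41.5),
        make_record(id="f2", series="finnish", sex="female", age_inclusion=25.0,
                    age_last_observation=30.0),
        make_record(id="f3", series="finnish", sex="female", age_inclusion=33.0,
                    age_last_observation=45.0, events=((40.0, "153"),), months=30),
        make_record(id="o1", series="other", sex="male", age_inclusion=35.0,
                    age_last_observation=50.0, events=((45.0, "182"),)),
        make_record(id="o2", series="other", sex="female", age_inclusion=30.0,
                    age_last_observation=44.0, events=((38.5, "153"),), months=14),
    ]


@pytest.fixture(scope="session")
def simulated_cohort():
    """A medium synthetic series with deaths, for structural tests."""
    cfg = SimulationConfig(n_patients=400, seed=20240901)
    return simulate_survival_after_cancer(cfg, simulate_cohort(cfg))
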