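import numpy as np
import pytest
from hypothesis import settings

from trauma_triage import (
    generate_parent_cohort,
    load_packaged_tools,
    population_config,
)
from trauma_triage.records import (
    AIS_REGIONS,
    MECHANISMS,
    SERVICES,
    IncidentRecord,
    Injury,
    VitalsMeasurement,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tools():
    return load_packaged_tools()


@pytest.fixture(scope="session")
def small_cohort():
    """4,000-incident cohort shared across unit tests."""
    return generate_parent_cohort(population_config(n_incidents=4_000, seed=11))


@pytest.fixture(scope="session")
def cohort_20k():
    """Study-scale cohort for cumulative-step and distribution checks."""
    return generate_parent_cohort(population_config(n_incidents=20_000, seed=20_260_927))


def make_record(
    record_id="R1",
    age=40.0,
    sbp=(120.0,),
    rr=(16.0,),
    spo2=(98.0,),
    gcs=(15,),
    mechanism="fall_lt_1m",
    injuries=(),
    interventions=(),
    special=(),
    service="LAS",
    prealert=False,
    destination=None,
    report_form_id="PRF1",
):
    """Hand-build an incident record with aligned vitals series."""
    n = len(sbp)
    vitals = [
        VitalsMeasurement(
            time_min=5.0 * k, sbp=sbp[k], rr=rr[k], spo2=spo2[k], gcs=gcs[k]
        )
        for k in range(n)
    ]
    return IncidentRecord(
        record_id=record_id,
        report_form_id=report_form_id,
        age_years=age,
        sex="female",
        mechanism=mechanism,
        service=service,
        vitals=vitals,
        injuries=list(injuries),
        interventions=frozenset(interventions),
        special_circumstances=frozenset(special),
        provider_prealert_mtc=prealert,
        destination_mtc=prealert if destination is None else destination,
    )


def fuzz_record(rng: np.random.Generator, record_id: str) -> IncidentRecord:
    """A random but structurally valid record for oracle-equivalence fuzzing."""
    n_meas = int(rng.integers(1, 5))
    vitals = [
        VitalsMeasurement(
            time_min=5.0 * k,
            sbp=float(rng.integers(40, 220)),
            rr=float(rng.integers(4, 45)),
            spo2=float(rng.integers(60, 101)),
            gcs=int(rng.integers(3, 16)),
        )
        for k in range(n_meas)
    ]
    injuries = [
        Injury(
            region=str(rng.choice(AIS_REGIONS)),
            severity=int(rng.integers(1, 6)),
            open_fracture=bool(rng.random() < 0.2),
        )
        for _ in range(int(rng.integers(0, 5)))
    ]
    special = frozenset({"anticoagulant_use"}) if rng.random() < 0.3 else frozenset()
    return IncidentRecord(
        record_id=record_id,
        age_years=float(rng.integers(0, 103)),
        sex="male",
        mechanism=str(rng.choice(MECHANISMS)),
        service=str(rng.choice(SERVICES)),
        vitals=vitals,
        injuries=injuries,
        interventions=frozenset({"intubation"}) if rng.random() < 0.2 else frozenset(),
        special_circumstances=special,
        provider_prealert_mtc=bool(rng.random() < 0.3),
        destination_mtc=bool(rng.random() < 0.4),
    )
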