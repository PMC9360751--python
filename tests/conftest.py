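import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csfdecay.domain import BloodCount, Cohort, Complication, CSFSample, Patient
from csfdecay.synthetic import default_config, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_patient(pid, days, values, outcome=None, drainage_rate=200.0, blood=None):
    """Small hand-built patient: same value sequence for all three analytes."""
    blood = blood or BloodCount(rbc_blood=4.5e6, wbc_blood=8000.0)
    comps = {o: Complication(False) for o in ("rebleeding", "ventriculitis", "dci")}
    if outcome:
        comps[outcome] = Complication(True, 5.0)
    samples = [
        CSFSample(
            patient_id=pid,
            day=float(d),
            rbc_csf=float(v),
            wbc_csf=float(v),
            tp=float(v),
            blood=blood,
            cum_drainage=drainage_rate * d,
        )
        for d, v in zip(days, values)
    ]
    return Patient(patient_id=pid, age=60.0, sex="F", samples=samples, **comps)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def reference_cohort(config):
    return generate_cohort(config, seed=42)


@pytest.fixture()
def flat_cohort():
    """Three patients whose every analyte equals 100 at every visit."""
    return Cohort(
        [
            make_patient("A", [2, 6, 10, 14], [100] * 4),
            make_patient("B", [3, 7, 11], [100] * 3),
            make_patient("C", [1, 8, 12, 20], [100] * 4),
        ]
    )
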