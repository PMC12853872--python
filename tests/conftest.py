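import numpy as np
import pytest

from abburden import (
    ABBCutoffs,
    BreastMeasurement,
    CohortSpec,
    PatientRecord,
    SchnurTable,
    generate_cohort,
)


@pytest.fixture(scope="session")
def schnur_table() -> SchnurTable:
    return SchnurTable.default()


@pytest.fixture
def cutoffs() -> ABBCutoffs:
    return ABBCutoffs()


def make_patient(
    patient_id="p1",
    age=45.0,
    height=1.65,
    weight=75.0,
    has_symptom=True,
    has_finding=True,
    **breast_kwargs,
) -> PatientRecord:
    """One-breast patient with sane defaults, overridable per test."""
    defaults = dict(
        side="left",
        sn_n=30.0,
        n_imf=14.0,
        base_width=16.0,
        ptosis_grade=3.0,
        resection_weight=450.0,
    )
    defaults.update(breast_kwargs)
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        height=height,
        weight=weight,
        breasts=(BreastMeasurement(**defaults),),
        has_symptom=has_symptom,
        has_finding=has_finding,
    )


def random_cohort(rng: np.random.Generator, n: int) -> list[PatientRecord]:
    """Small unstructured random cohort for oracle-equivalence tests."""
    patients = []
    for i in range(n):
        patients.append(
            make_patient(
                patient_id=f"r{i}",
                height=float(rng.uniform(1.45, 1.85)),
                weight=float(rng.uniform(50, 120)),
                sn_n=float(rng.uniform(22.5, 40)),
                n_imf=float(rng.uniform(9, 22)),
                base_width=float(rng.uniform(12, 24)),
                ptosis_grade=float(rng.choice([0.0, 1.0, 2.0, 2.5, 3.0])),
                resection_weight=float(rng.uniform(90, 1200)),
            )
        )
    return patients


@pytest.fixture(scope="session")
def default_cohort() -> list[PatientRecord]:
    return generate_cohort(CohortSpec(n=84, seed=11))
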