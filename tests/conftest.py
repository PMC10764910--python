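"""Shared fixtures: compact builders for patients, prescriptions and timelines."""

from __future__ import annotations

import datetime as dt

import pytest

from statinsim import (
    DiagnosisCategory,
    DiagnosisEvent,
    DrugClass,
    LabMeasurement,
    PatientRecord,
    PrescriptionEvent,
    SelectionConfig,
    Sex,
    StatinCatalog,
)

INDEX = dt.date(2021, 5, 1)


@pytest.fixture
def config() -> SelectionConfig:
    return SelectionConfig()

@pytest.fixture
def catalog() -> StatinCatalog:
    return StatinCatalog()


def rx(
    days_before_index: int,
    molecule: str = "simvastatin",
    dose: float = 40.0,
    drug_class: DrugClass = DrugClass.statin,
    supply: int | None = 90,
    pid: str = "P1",
    index: dt.date = INDEX,
) -> PrescriptionEvent:
    return PrescriptionEvent(
        pid, index - dt.timedelta(days=days_before_index), drug_class, molecule, dose, supply
    )


def lab(days_before_index: int, value: float, pid: str = "P1", index: dt.date = INDEX):
    return LabMeasurement(pid, index - dt.timedelta(days=days_before_index), "ldl_c", value)


def dx(days_before_index: int, category: DiagnosisCategory, pid: str = "P1", index: dt.date = INDEX):
    return DiagnosisEvent(pid, index - dt.timedelta(days=days_before_index), category)


def patient(
    prescriptions=(),
    labs=(),
    diagnoses=(),
    pid: str = "P1",
    sex: Sex = Sex.female,
    age: float = 70.0,
) -> PatientRecord:
    record = PatientRecord(
        patient_id=pid,
        sex=sex,
        age_years=age,
        prescriptions=list(prescriptions),
        labs=list(labs),
        diagnoses=list(diagnoses),
    )
    record.sort_events()
    return record


def quarterly(first: int, last: int, step: int = 90, **kwargs):
    """Prescriptions every ``step`` days from ``first`` down to ``last`` days before index."""
    return [rx(d, **kwargs) for d in range(first, last - 1, -step)]
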