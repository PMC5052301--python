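"""Shared fixtures: the default registry and record-level toy builders."""

from __future__ import annotations

import datetime as dt

import pytest

from qibench import load_registry
from qibench.engine import (
    Observation,
    PatientRecord,
    PracticeExtract,
    Prescription,
)
from qibench.registry import Disease

REF = dt.date(2012, 7, 1)  # reference date used by most toy fixtures


@pytest.fixture(scope="session")
def registry():
    return load_registry()


def make_patient(
    pid: str,
    *,
    visit_days_ago=(30,),
    diseases=(),
    obs=(),
    rx=(),
    ref: dt.date = REF,
) -> PatientRecord:
    """Build a patient relative to a reference date.

    ``diseases`` are disease codes (diagnosis recorded 3 years ago);
    ``obs`` are (obs_type, value, days_ago); ``rx`` are
    (drug_class, days_ago).
    """
    return PatientRecord(
        patient_id=pid,
        encounter_dates=frozenset(
            ref - dt.timedelta(days=d) for d in visit_days_ago
        ),
        diagnoses=frozenset(
            (Disease(d), ref - dt.timedelta(days=3 * 365)) for d in diseases
        ),
        observations=tuple(
            Observation(t, v, ref - dt.timedelta(days=d)) for t, v, d in obs
        ),
        prescriptions=tuple(
            Prescription(c, ref - dt.timedelta(days=d)) for c, d in rx
        ),
    )


def make_extract(
    gp_id: str,
    patients,
    *,
    wave: str = "2012",
    ref: dt.date = REF,
    capability=None,
) -> PracticeExtract:
    kwargs = {} if capability is None else {"capability": capability}
    return PracticeExtract(
        gp_id=gp_id,
        region="test",
        wave=wave,
        reference_date=ref,
        patients=tuple(patients),
        **kwargs,
    )


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture
def extract_factory():
    return make_extract
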