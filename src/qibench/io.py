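"""Delimited-file interchange for record-level practice extracts.

Extracts are exchanged as four record tables plus one practice metadata
table, all plain CSV with ISO-8601 dates:

``practices.csv``
    wave, gp_id, region, reference_date, capability — capability is
    ``all``, ``prevalence_only`` or a semicolon-joined list of
    indicator kinds.
``patients.csv``
    wave, gp_id, patient_id, diagnoses — diagnoses are semicolon-joined
    ``DISEASE:recorded_date`` tokens (empty for undiagnosed patients).
``encounters.csv``
    wave, gp_id, patient_id, date.
``observations.csv``
    wave, gp_id, patient_id, obs_type, value, date.
``prescriptions.csv``
    wave, gp_id, patient_id, drug_class, date.

A generated cohort additionally carries ``true_values.csv`` (wave,
gp_id, indicator_id, expected_pct), the ground-truth sidecar.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import pandas as pd

from .engine import (
    ALL_KINDS,
    Observation,
    PatientRecord,
    PracticeExtract,
    Prescription,
    PREVALENCE_ONLY,
)
from .registry import Disease, IndicatorKind
from .synthetic import SyntheticCohort

__all__ = ["write_extracts", "read_extracts", "write_cohort", "read_true_values"]

_FILES = (
    "practices.csv",
    "patients.csv",
    "encounters.csv",
    "observations.csv",
    "prescriptions.csv",
)


def _capability_token(capability: frozenset[IndicatorKind]) -> str:
    if capability == ALL_KINDS:
        return "all"
    if capability == PREVALENCE_ONLY:
        return "prevalence_only"
    return ";".join(sorted(k.value for k in capability))


def _parse_capability(token: str) -> frozenset[IndicatorKind]:
    if token == "all":
        return ALL_KINDS
    if token == "prevalence_only":
        return PREVALENCE_ONLY
    return frozenset(IndicatorKind(t) for t in token.split(";") if t)


def write_extracts(
    extracts: Sequence[PracticeExtract], out_dir: str | Path
) -> None:
    """Write extracts (any mix of waves) as the five delimited tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    practices, patients, encounters, observations, prescriptions = (
        [] for _ in range(5)
    )
    for e in extracts:
        practices.append(
            {
                "wave": e.wave,
                "gp_id": e.gp_id,
                "region": e.region,
                "reference_date": e.reference_date.isoformat(),
                "capability": _capability_token(e.capability),
            }
        )
        for p in e.patients:
            patients.append(
                {
                    "wave": e.wave,
                    "gp_id": e.gp_id,
                    "patient_id": p.patient_id,
                    "diagnoses": ";".join(
                        f"{d.value}:{date.isoformat()}"
                        for d, date in sorted(
                            p.diagnoses, key=lambda x: (x[0].value, x[1])
                        )
                    ),
                }
            )
            for date in sorted(p.encounter_dates):
                encounters.append(
                    {
                        "wave": e.wave,
                        "gp_id": e.gp_id,
                        "patient_id": p.patient_id,
                        "date": date.isoformat(),
                    }
                )
            for o in p.observations:
                observations.append(
                    {
                        "wave": e.wave,
                        "gp_id": e.gp_id,
                        "patient_id": p.patient_id,
                        "obs_type": o.obs_type,
                        "value": "" if o.value is None else o.value,
                        "date": o.date.isoformat(),
                    }
                )
            for rx in p.prescriptions:
                prescriptions.append(
                    {
                        "wave": e.wave,
                        "gp_id": e.gp_id,
                        "patient_id": p.patient_id,
                        "drug_class": rx.drug_class,
                        "date": rx.date.isoformat(),
                    }
                )
    for name, rows, cols in (
        ("practices.csv", practices,
         ["wave", "gp_id", "region", "reference_date", "capability"]),
        ("patients.csv", patients, ["wave", "gp_id", "patient_id", "diagnoses"]),
        ("encounters.csv", encounters, ["wave", "gp_id", "patient_id", "date"]),
        ("observations.csv", observations,
         ["wave", "gp_id", "patient_id", "obs_type", "value", "date"]),
        ("prescriptions.csv", prescriptions,
         ["wave", "gp_id", "patient_id", "drug_class", "date"]),
    ):
        pd.DataFrame(rows, columns=cols).to_csv(out / name, index=False)


def _parse_diagnoses(token) -> frozenset[tuple[Disease, dt.date]]:
    if not isinstance(token, str) or not token:
        return frozenset()
    out = set()
    for part in token.split(";"):
        disease, _, date = part.partition(":")
        out.add((Disease(disease), dt.date.fromisoformat(date)))
    return frozenset(out)


def read_extracts(in_dir: str | Path) -> dict[str, list[PracticeExtract]]:
    """Read extracts back, grouped by wave label."""
    src = Path(in_dir)
    missing = [f for f in _FILES if not (src / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing extract tables in {src}: {missing}")
    frames = {
        f: pd.read_csv(src / f, dtype={"wave": str, "gp_id": str, "patient_id": str})
        for f in _FILES
    }
    enc_by = {
        k: g for k, g in frames["encounters.csv"].groupby(["wave", "gp_id", "patient_id"])
    }
    obs_by = {
        k: g
        for k, g in frames["observations.csv"].groupby(["wave", "gp_id", "patient_id"])
    }
    rx_by = {
        k: g
        for k, g in frames["prescriptions.csv"].groupby(["wave", "gp_id", "patient_id"])
    }
    pat_by = {
        k: g for k, g in frames["patients.csv"].groupby(["wave", "gp_id"])
    }
    out: dict[str, list[PracticeExtract]] = {}
    for row in frames["practices.csv"].itertuples(index=False):
        wave, gp = str(row.wave), str(row.gp_id)
        patients = []
        for prow in pat_by.get((wave, gp), pd.DataFrame()).itertuples(index=False):
            pid = str(prow.patient_id)
            key = (wave, gp, pid)
            enc = frozenset(
                dt.date.fromisoformat(d) for d in enc_by.get(key, pd.DataFrame({"date": []}))["date"]
            )
            observations = tuple(
                Observation(
                    obs_type=str(o.obs_type),
                    value=(
                        None
                        if (isinstance(o.value, float) and pd.isna(o.value))
                        or o.value == ""
                        else (
                            float(o.value)
                            if not isinstance(o.value, str)
                            or o.value.replace(".", "", 1).replace("-", "", 1).isdigit()
                            else str(o.value)
                        )
                    ),
                    date=dt.date.fromisoformat(str(o.date)),
                )
                for o in obs_by.get(key, pd.DataFrame()).itertuples(index=False)
            )
            prescriptions = tuple(
                Prescription(
                    drug_class=str(r.drug_class),
                    date=dt.date.fromisoformat(str(r.date)),
                )
                for r in rx_by.get(key, pd.DataFrame()).itertuples(index=False)
            )
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    encounter_dates=enc,
                    diagnoses=_parse_diagnoses(prow.diagnoses),
                    observations=observations,
                    prescriptions=prescriptions,
                )
            )
        out.setdefault(wave, []).append(
            PracticeExtract(
                gp_id=gp,
                region=str(row.region),
                wave=wave,
                reference_date=dt.date.fromisoformat(str(row.reference_date)),
                patients=tuple(patients),
                capability=_parse_capability(str(row.capability)),
            )
        )
    return out


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write all waves of a generated cohort plus the ground-truth sidecar."""
    out = Path(out_dir)
    all_extracts = [e for wave in cohort.wave_labels for e in cohort.extracts[wave]]
    write_extracts(all_extracts, out)
    pd.DataFrame(
        [
            {"wave": w, "gp_id": g, "indicator_id": i, "expected_pct": v}
            for (w, g, i), v in sorted(cohort.true_pct.items())
        ]
    ).to_csv(out / "true_values.csv", index=False)


def read_true_values(in_dir: str | Path) -> dict[tuple[str, str, str], float]:
    frame = pd.read_csv(
        Path(in_dir) / "true_values.csv", dtype={"wave": str, "gp_id": str}
    )
    return {
        (str(r.wave), str(r.gp_id), str(r.indicator_id)): float(r.expected_pct)
        for r in frame.itertuples(index=False)
    }
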