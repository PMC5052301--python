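"""Per-practice indicator achievement from record-level data.

Achievement for an indicator is the percentage of denominator patients
who satisfy its criterion within the lookback window before the
practice's extraction reference date.  The denominator is normally the
diagnosed patients who visited the practice within the last 15 months
("eligible" patients — chronic patients usually see their GP at least
once a year, plus a tolerance quarter).  Two diabetes indicators are
conditional: glycaemic control (HbA1c < 7.5 %) is computed among
diagnosed patients with an HbA1c measurement in the last 9 months, and
metformin prescription among those whose measured HbA1c was above
target.

Prevalence is the share of eligible diagnosed patients among all
patients seen in the 15-month window, optionally deflated by the
fraction of the population that visits a GP at all (``visit_coverage``),
since visitor-based prevalence overstates population prevalence.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as dt
import enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .registry import (
    DenominatorRule,
    Disease,
    IndicatorDefinition,
    IndicatorKind,
    IndicatorRegistry,
)

__all__ = [
    "Observation",
    "Prescription",
    "PatientRecord",
    "PracticeExtract",
    "MissingReason",
    "Cell",
    "AchievementTable",
    "ALL_KINDS",
    "PREVALENCE_ONLY",
    "HBA1C_TARGET",
    "HBA1C_WINDOW_MONTHS",
    "ELIGIBILITY_WINDOW_MONTHS",
    "months_before",
    "in_window",
    "eligible_patients",
    "compute_prevalence",
    "adjust_prevalence",
    "compute_achievement",
    "build_achievement_table",
    "apply_exclusions",
]

#: HbA1c control target in percent (glycated-haemoglobin units).
HBA1C_TARGET = 7.5
#: Window for HbA1c-based conditional denominators, months.
HBA1C_WINDOW_MONTHS = 9
#: Visit window defining the treated population, months.
ELIGIBILITY_WINDOW_MONTHS = 15

OBS_TYPES = frozenset(
    {"bmi", "blood_pressure", "smoking_status", "creatinine", "hba1c", "spirometry"}
)
DRUG_CLASSES = frozenset(
    {"metformin", "statin", "beta_blocker", "ace_arb", "antithrombotic"}
)

ALL_KINDS = frozenset(IndicatorKind)
#: Capability profile of record systems that only export disease counts.
PREVALENCE_ONLY = frozenset({IndicatorKind.PREVALENCE})


# --------------------------------------------------------------------------
# record-level data types
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Observation:
    obs_type: str  # one of OBS_TYPES
    value: float | str | None
    date: dt.date


@dataclasses.dataclass(frozen=True)
class Prescription:
    drug_class: str  # one of DRUG_CLASSES
    date: dt.date


@dataclasses.dataclass
class PatientRecord:
    """All extractable records for one patient.

    Diagnoses are (disease, recorded_date) pairs and are treated as
    permanent once recorded — the targeted conditions are chronic.
    """

    patient_id: str
    encounter_dates: frozenset[dt.date] = frozenset()
    diagnoses: frozenset[tuple[Disease, dt.date]] = frozenset()
    observations: tuple[Observation, ...] = ()
    prescriptions: tuple[Prescription, ...] = ()

    def has_diagnosis(self, disease: Disease, on_or_before: dt.date) -> bool:
        return any(
            d is disease and recorded <= on_or_before
            for d, recorded in self.diagnoses
        )


@dataclasses.dataclass
class PracticeExtract:
    """One practice's extract at one wave.

    ``reference_date`` anchors every lookback window; ``capability`` is
    the set of indicator kinds the practice's record system can export
    (heterogeneous EHRs — some systems only export prevalences).
    """

    gp_id: str
    region: str
    wave: str
    reference_date: dt.date
    patients: tuple[PatientRecord, ...]
    capability: frozenset[IndicatorKind] = ALL_KINDS

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.gp_id}: duplicate patient ids")


class MissingReason(str, enum.Enum):
    PREVALENCE_ZERO = "prevalence_zero"
    INVALID_VALUE = "invalid_value"
    CAPABILITY = "capability"
    EMPTY_DENOMINATOR = "empty_denominator"


@dataclasses.dataclass(frozen=True)
class Cell:
    """One (practice, indicator) achievement value or a missing marker."""

    numerator: Optional[int] = None
    denominator: Optional[int] = None
    pct: Optional[float] = None
    missing_reason: Optional[MissingReason] = None

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not None

    @staticmethod
    def missing(reason: MissingReason) -> "Cell":
        return Cell(missing_reason=reason)

    @staticmethod
    def valued(numerator: int, denominator: int, pct: float | None = None) -> "Cell":
        if pct is None:
            pct = 100.0 * numerator / denominator
        return Cell(numerator=numerator, denominator=denominator, pct=pct)


@dataclasses.dataclass
class AchievementTable:
    """GP × indicator matrix of achievement percentages for one wave."""

    wave: str
    cells: dict[tuple[str, str], Cell]  # (gp_id, indicator_id) -> Cell
    gp_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]

    def cell(self, gp_id: str, indicator_id: str) -> Cell:
        return self.cells[(gp_id, indicator_id)]

    def values_for(self, indicator_id: str) -> dict[str, float]:
        """Non-missing achievement values, keyed by gp_id."""
        return {
            gp: c.pct
            for gp in self.gp_ids
            if not (c := self.cells[(gp, indicator_id)]).is_missing
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gp in self.gp_ids:
            for ind in self.indicator_ids:
                c = self.cells[(gp, ind)]
                rows.append(
                    {
                        "wave": self.wave,
                        "gp_id": gp,
                        "indicator_id": ind,
                        "numerator": c.numerator,
                        "denominator": c.denominator,
                        "pct": c.pct,
                        "missing_reason": (
                            c.missing_reason.value if c.missing_reason else None
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "AchievementTable":
        waves = frame["wave"].astype(str).unique()
        if len(waves) != 1:
            raise ValueError("achievement frame must hold exactly one wave")
        cells: dict[tuple[str, str], Cell] = {}
        gp_ids: list[str] = []
        indicator_ids: list[str] = []
        for row in frame.itertuples(index=False):
            gp, ind = str(row.gp_id), str(row.indicator_id)
            if gp not in gp_ids:
                gp_ids.append(gp)
            if ind not in indicator_ids:
                indicator_ids.append(ind)
            if isinstance(row.missing_reason, str) and row.missing_reason:
                cells[(gp, ind)] = Cell.missing(MissingReason(row.missing_reason))
            else:
                cells[(gp, ind)] = Cell(
                    numerator=None if pd.isna(row.numerator) else int(row.numerator),
                    denominator=(
                        None if pd.isna(row.denominator) else int(row.denominator)
                    ),
                    pct=float(row.pct),
                )
        return AchievementTable(
            wave=str(waves[0]),
            cells=cells,
            gp_ids=tuple(gp_ids),
            indicator_ids=tuple(indicator_ids),
        )


# --------------------------------------------------------------------------
# calendar arithmetic
# --------------------------------------------------------------------------

def months_before(date: dt.date, months: int) -> dt.date:
    """The calendar date ``months`` months before ``date``.

    Day-of-month overflow is clipped to the last day of the target month
    (e.g. 31 March minus 1 month -> 28/29 February).
    """
    year = date.year
    month = date.month - months
    while month < 1:
        month += 12
        year -= 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def in_window(
    date: dt.date, reference: dt.date, lookback_months: Optional[int]
) -> bool:
    """Whether ``date`` falls inside the half-open window (ref − N months, ref].

    ``lookback_months=None`` means any time up to the reference date.
    """
    if date > reference:
        return False
    if lookback_months is None:
        return True
    return date > months_before(reference, lookback_months)


# --------------------------------------------------------------------------
# denominators and criteria
# --------------------------------------------------------------------------

def _visitors(extract: PracticeExtract) -> list[PatientRecord]:
    ref = extract.reference_date
    return [
        p
        for p in extract.patients
        if any(in_window(d, ref, ELIGIBILITY_WINDOW_MONTHS) for d in p.encounter_dates)
    ]


def eligible_patients(
    extract: PracticeExtract, disease: Disease | str
) -> list[PatientRecord]:
    """Diagnosed patients with an encounter in the 15-month visit window."""
    disease = Disease(disease)
    ref = extract.reference_date
    return [
        p
        for p in _visitors(extract)
        if p.has_diagnosis(disease, on_or_before=ref)
    ]


def compute_prevalence(extract: PracticeExtract, disease: Disease | str) -> float:
    """Raw visitor-based prevalence of ``disease`` in percent.

    Denominator: all patients seen in the 15-month window.  Raises
    ``ValueError`` for an empty practice (no visitors).
    """
    visitors = _visitors(extract)
    if not visitors:
        raise ValueError(
            f"{extract.gp_id}: no patients with an encounter in the "
            f"{ELIGIBILITY_WINDOW_MONTHS}-month window"
        )
    return 100.0 * len(eligible_patients(extract, disease)) / len(visitors)


def adjust_prevalence(raw_pct: float, visit_coverage: float) -> float:
    """Deflate visitor-based prevalence to approximate population prevalence.

    ``visit_coverage`` is the fraction of the population that visits a GP
    within the window; cases are assumed fully captured among visitors,
    so the population denominator is inflated by 1/coverage.
    """
    if not 0.0 <= raw_pct <= 100.0:
        raise ValueError(f"raw prevalence {raw_pct} outside [0, 100]")
    if not 0.0 < visit_coverage <= 1.0:
        raise ValueError(f"visit_coverage {visit_coverage} outside (0, 1]")
    return raw_pct * visit_coverage


def _hba1c_in_window(patient: PatientRecord, ref: dt.date) -> list[float]:
    return [
        float(o.value)
        for o in patient.observations
        if o.obs_type == "hba1c"
        and o.value is not None
        and in_window(o.date, ref, HBA1C_WINDOW_MONTHS)
    ]


def _satisfies_criterion(
    patient: PatientRecord, definition: IndicatorDefinition, ref: dt.date
) -> bool:
    crit = definition.criterion
    window = definition.lookback_months
    obs_for = {
        "bmi_recorded": "bmi",
        "bp_recorded": "blood_pressure",
        "smoking_recorded": "smoking_status",
        "creatinine_done": "creatinine",
        "hba1c_done": "hba1c",
        "spirometry_recorded": "spirometry",
    }
    rx_for = {
        "metformin_if_high": "metformin",
        "statin_rx": "statin",
        "beta_blocker_rx": "beta_blocker",
        "ace_arb_rx": "ace_arb",
        "antithrombotic_rx": "antithrombotic",
    }
    if crit in obs_for:
        return any(
            o.obs_type == obs_for[crit] and in_window(o.date, ref, window)
            for o in patient.observations
        )
    if crit in rx_for:
        return any(
            rx.drug_class == rx_for[crit] and in_window(rx.date, ref, window)
            for rx in patient.prescriptions
        )
    if crit == "hba1c_below_target":
        return any(v < HBA1C_TARGET for v in _hba1c_in_window(patient, ref))
    raise ValueError(f"unknown criterion {crit!r}")


def _denominator(
    extract: PracticeExtract, definition: IndicatorDefinition
) -> list[PatientRecord]:
    ref = extract.reference_date
    rule = definition.denominator_rule
    if rule is DenominatorRule.ALL_PATIENTS:
        return _visitors(extract)
    diagnosed = eligible_patients(extract, definition.disease)
    if rule is DenominatorRule.DIAGNOSED:
        return diagnosed
    if rule is DenominatorRule.DIAGNOSED_MEASURED:
        return [p for p in diagnosed if _hba1c_in_window(p, ref)]
    if rule is DenominatorRule.DIAGNOSED_MEASURED_ABOVE_TARGET:
        # "above target" = any in-window HbA1c >= 7.5 (mirror of the
        # below-target indicator, which also accepts any in-window value)
        return [
            p
            for p in diagnosed
            if any(v >= HBA1C_TARGET for v in _hba1c_in_window(p, ref))
        ]
    raise ValueError(f"unknown denominator rule {rule}")


def compute_achievement(
    extract: PracticeExtract,
    definition: IndicatorDefinition,
    visit_coverage: float = 1.0,
) -> Cell:
    """Achievement cell for one indicator at one practice.

    Prevalence indicators return the coverage-adjusted prevalence with
    the raw eligible/visitor counts.  A record system that cannot export
    the indicator kind yields ``missing(capability)``; an empty
    denominator yields ``missing(empty_denominator)``.
    """
    if definition.kind not in extract.capability:
        return Cell.missing(MissingReason.CAPABILITY)
    if definition.kind is IndicatorKind.PREVALENCE:
        visitors = _visitors(extract)
        if not visitors:
            return Cell.missing(MissingReason.EMPTY_DENOMINATOR)
        n_cases = len(eligible_patients(extract, definition.disease))
        raw = 100.0 * n_cases / len(visitors)
        return Cell.valued(
            n_cases, len(visitors), pct=adjust_prevalence(raw, visit_coverage)
        )
    denom = _denominator(extract, definition)
    if not denom:
        return Cell.missing(MissingReason.EMPTY_DENOMINATOR)
    ref = extract.reference_date
    num = sum(_satisfies_criterion(p, definition, ref) for p in denom)
    return Cell.valued(num, len(denom))


def build_achievement_table(
    extracts: Sequence[PracticeExtract],
    registry: IndicatorRegistry,
    visit_coverage: float = 1.0,
) -> AchievementTable:
    """One cell per (practice, indicator), exclusion rules applied."""
    if not extracts:
        raise ValueError("no practice extracts supplied")
    waves = {e.wave for e in extracts}
    if len(waves) != 1:
        raise ValueError(f"extracts span multiple waves: {sorted(waves)}")
    gp_ids = [e.gp_id for e in extracts]
    if len(gp_ids) != len(set(gp_ids)):
        raise ValueError("duplicate gp_id among extracts")
    cells = {
        (e.gp_id, d.indicator_id): compute_achievement(e, d, visit_coverage)
        for e in extracts
        for d in registry
    }
    table = AchievementTable(
        wave=waves.pop(),
        cells=cells,
        gp_ids=tuple(gp_ids),
        indicator_ids=tuple(registry.indicator_ids),
    )
    return apply_exclusions(table, registry)


def apply_exclusions(
    table: AchievementTable, registry: IndicatorRegistry
) -> AchievementTable:
    """Apply the analysis exclusion rules; idempotent.

    A disease with prevalence 0 at a practice has all its dependent
    (non-prevalence) indicators marked missing there, and any cell with
    an impossible percentage (outside [0, 100], as can arise from manual
    extraction errors in real data) is marked invalid.
    """
    cells = dict(table.cells)
    prevalence_ids = {
        d.disease: d.indicator_id
        for d in registry
        if d.kind is IndicatorKind.PREVALENCE
    }
    for gp in table.gp_ids:
        for disease, prev_id in prevalence_ids.items():
            prev = cells.get((gp, prev_id))
            if prev is None or prev.is_missing or prev.pct != 0.0:
                continue
            for d in registry.for_disease(disease):
                if d.kind is IndicatorKind.PREVALENCE:
                    continue
                key = (gp, d.indicator_id)
                if key not in cells:
                    continue
                c = cells[key]
                # an empty denominator here IS the prevalence-zero case;
                # capability gaps keep their own reason
                if (
                    not c.is_missing
                    or c.missing_reason is MissingReason.EMPTY_DENOMINATOR
                ):
                    cells[key] = Cell.missing(MissingReason.PREVALENCE_ZERO)
    for key, c in cells.items():
        if not c.is_missing and c.pct is not None and not 0.0 <= c.pct <= 100.0:
            cells[key] = Cell.missing(MissingReason.INVALID_VALUE)
    return AchievementTable(
        wave=table.wave,
        cells=cells,
        gp_ids=table.gp_ids,
        indicator_ids=table.indicator_ids,
    )
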