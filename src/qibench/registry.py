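"""Catalogue of chronic-disease quality indicators.

A quality indicator (QI) is a measurable element of practice performance:
a numerator criterion, a denominator population and a lookback window,
plus consensus quality standards (acceptable and ideal achievement
percentages).  The default registry ships 43 indicators covering eight
chronic diseases (type 2 diabetes, hypertension, coronary heart disease,
cerebrovascular disease, peripheral arterial disease, chronic heart
failure, atrial fibrillation and COPD): one prevalence indicator per
disease plus documentation, measurement, threshold and prescription
indicators.  The 35 non-prevalence indicators feed the quality score.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Disease",
    "IndicatorKind",
    "DenominatorRule",
    "IndicatorDefinition",
    "IndicatorRegistry",
    "RegistryError",
    "load_registry",
    "standards_for",
]


class RegistryError(ValueError):
    """Raised for malformed or inconsistent indicator registries."""


class Disease(str, enum.Enum):
    DM2 = "DM2"
    HT = "HT"
    CHD = "CHD"
    CBVD = "CBVD"
    PAD = "PAD"
    CHF = "CHF"
    AF = "AF"
    COPD = "COPD"


class IndicatorKind(str, enum.Enum):
    PREVALENCE = "prevalence"
    DOCUMENTATION = "documentation"
    MEASUREMENT = "measurement"
    THRESHOLD = "threshold"
    PRESCRIPTION = "prescription"
    CONDITIONAL_PRESCRIPTION = "conditional_prescription"
    EVER_RECORDED = "ever_recorded"


#: Indicator kinds whose denominator depends on another indicator's outcome.
CONDITIONAL_KINDS = frozenset(
    {IndicatorKind.THRESHOLD, IndicatorKind.CONDITIONAL_PRESCRIPTION}
)


class DenominatorRule(str, enum.Enum):
    ALL_PATIENTS = "all_patients"
    DIAGNOSED = "diagnosed"
    DIAGNOSED_MEASURED = "diagnosed_measured"
    DIAGNOSED_MEASURED_ABOVE_TARGET = "diagnosed_measured_above_target"


class IndicatorDefinition(BaseModel):
    """One quality indicator.

    Parameters mirror the registry file: a stable id, the disease the
    indicator belongs to, the criterion predicate evaluated per patient,
    the lookback window in calendar months (``None`` = any time, used for
    spirometry), the denominator rule, the quality-standard pair and
    whether the indicator contributes to the quality score.
    """

    model_config = ConfigDict(frozen=True)

    indicator_id: str
    disease: Disease
    label: str
    kind: IndicatorKind
    lookback_months: Optional[int] = None
    criterion: str
    denominator_rule: DenominatorRule
    acceptable_pct: Optional[float] = None
    ideal_pct: Optional[float] = None
    in_score: bool

    @field_validator("lookback_months")
    @classmethod
    def _positive_window(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v <= 0:
            raise ValueError("lookback_months must be positive or null")
        return v

    @field_validator("acceptable_pct", "ideal_pct")
    @classmethod
    def _pct_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 <= v <= 100.0:
            raise ValueError("quality standards must lie in [0, 100]")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "IndicatorDefinition":
        if (
            self.acceptable_pct is not None
            and self.ideal_pct is not None
            and self.ideal_pct < self.acceptable_pct
        ):
            raise ValueError(
                f"{self.indicator_id}: ideal_pct ({self.ideal_pct}) below "
                f"acceptable_pct ({self.acceptable_pct})"
            )
        if self.kind in CONDITIONAL_KINDS and self.disease is not Disease.DM2:
            raise ValueError(
                f"{self.indicator_id}: conditional indicator kinds are only "
                "defined for DM2"
            )
        if self.kind is IndicatorKind.PREVALENCE and self.in_score:
            raise ValueError(
                f"{self.indicator_id}: prevalence indicators never enter the score"
            )
        return self


class IndicatorRegistry(BaseModel):
    """Ordered, validated collection of indicator definitions.

    Ordering is stable and drives report and table layout.
    """

    model_config = ConfigDict(frozen=True)

    version: str = "1.0"
    definitions: tuple[IndicatorDefinition, ...]

    @model_validator(mode="after")
    def _unique_ids(self) -> "IndicatorRegistry":
        ids = [d.indicator_id for d in self.definitions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate indicator ids: {sorted(dupes)}")
        return self

    def __iter__(self) -> Iterator[IndicatorDefinition]:  # type: ignore[override]
        return iter(self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        for d in self.definitions:
            if d.indicator_id == indicator_id:
                return d
        raise KeyError(indicator_id)

    @property
    def indicator_ids(self) -> list[str]:
        return [d.indicator_id for d in self.definitions]

    @property
    def scored(self) -> list[IndicatorDefinition]:
        """The indicators that contribute to the quality score."""
        return [d for d in self.definitions if d.in_score]

    @property
    def max_score(self) -> int:
        return 5 * len(self.scored)

    def for_disease(self, disease: Disease | str) -> list[IndicatorDefinition]:
        disease = Disease(disease)
        return [d for d in self.definitions if d.disease is disease]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "indicators": [
                {
                    **d.model_dump(mode="json"),
                }
                for d in self.definitions
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _default_registry_text() -> str:
    return (
        resources.files("qibench.data").joinpath("default_registry.yaml").read_text()
    )


def load_registry(source: str | Path | dict | None = None) -> IndicatorRegistry:
    """Load and validate an indicator registry.

    With ``source=None`` the built-in default registry (43 indicators,
    35 scored) is returned.  ``source`` may also be a path to a YAML
    document or an already-parsed mapping with ``version`` and
    ``indicators`` keys.

    Raises
    ------
    RegistryError
        If the document cannot be parsed or violates a registry
        invariant (duplicate ids, ideal below acceptable, ...).
    """
    if source is None:
        doc = yaml.safe_load(_default_registry_text())
    elif isinstance(source, dict):
        doc = source
    else:
        try:
            doc = yaml.safe_load(Path(source).read_text())
        except yaml.YAMLError as exc:
            raise RegistryError(f"unparseable registry document: {exc}") from exc
    if not isinstance(doc, dict) or "indicators" not in doc:
        raise RegistryError("registry document must contain an 'indicators' list")
    try:
        return IndicatorRegistry(
            version=str(doc.get("version", "1.0")),
            definitions=tuple(
                IndicatorDefinition(**row) for row in doc["indicators"]
            ),
        )
    except (TypeError, ValueError) as exc:
        raise RegistryError(str(exc)) from exc


def standards_for(
    registry: IndicatorRegistry, indicator_id: str
) -> tuple[Optional[float], Optional[float]]:
    """Return ``(acceptable_pct, ideal_pct)`` for one indicator.

    Raises ``KeyError`` for unknown ids.
    """
    d = registry[indicator_id]
    return (d.acceptable_pct, d.ideal_pct)
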