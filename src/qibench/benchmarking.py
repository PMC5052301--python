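"""Audit-and-feedback artifacts: self-audit, peer benchmarking, standards.

After each extraction wave every practice receives a report with its own
achievement per indicator (self-audit), the anonymised values of its
peers (benchmarking), the regional median, and a classification against
the consensus quality standards (below acceptable / acceptable / ideal).
Peer values are stripped of identifiers and shuffled per report so no
value can be traced to a colleague.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import AchievementTable
from .registry import IndicatorRegistry

__all__ = [
    "StandardClass",
    "IndicatorFeedback",
    "BenchmarkReport",
    "classify_standard",
    "regional_summary",
    "build_reports",
]


class StandardClass(str, enum.Enum):
    BELOW_ACCEPTABLE = "below_acceptable"
    ACCEPTABLE = "acceptable"
    IDEAL = "ideal"
    NOT_AVAILABLE = "not_available"


def classify_standard(
    pct: Optional[float],
    acceptable: Optional[float],
    ideal: Optional[float],
) -> StandardClass:
    """Classify an achievement against the (acceptable, ideal) standards.

    Boundaries are inclusive at the lower edge: pct == acceptable is
    acceptable, pct == ideal is ideal.  A missing value or missing
    standards give ``not_available``.
    """
    if pct is None or acceptable is None or ideal is None:
        return StandardClass.NOT_AVAILABLE
    if acceptable > ideal:
        raise ValueError("acceptable standard exceeds ideal standard")
    if pct >= ideal:
        return StandardClass.IDEAL
    if pct >= acceptable:
        return StandardClass.ACCEPTABLE
    return StandardClass.BELOW_ACCEPTABLE


def regional_summary(
    table: AchievementTable, quantile_method: str = "linear"
) -> pd.DataFrame:
    """Median, Q1 and Q3 per indicator over non-missing practices.

    ``quantile_method`` is any numpy quantile interpolation rule; the
    default (linear interpolation between order statistics) is the
    common statistics-package convention.  Indicators with no value are
    marked not available (NaN summaries, n = 0).
    """
    rows = []
    for ind in table.indicator_ids:
        values = list(table.values_for(ind).values())
        if values:
            q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=quantile_method)
            rows.append(
                {"indicator_id": ind, "median": med, "q1": q1, "q3": q3,
                 "n": len(values), "available": True}
            )
        else:
            rows.append(
                {"indicator_id": ind, "median": np.nan, "q1": np.nan, "q3": np.nan,
                 "n": 0, "available": False}
            )
    return pd.DataFrame(rows).set_index("indicator_id")


@dataclasses.dataclass(frozen=True)
class IndicatorFeedback:
    indicator_id: str
    own_pct: Optional[float]
    peer_pcts: tuple[float, ...]  # anonymised, shuffled, own value excluded
    regional_median: Optional[float]
    acceptable_pct: Optional[float]
    ideal_pct: Optional[float]
    standard_class: StandardClass


@dataclasses.dataclass(frozen=True)
class BenchmarkReport:
    """One practice's feedback for one wave."""

    gp_id: str
    wave: str
    feedback: tuple[IndicatorFeedback, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "wave": self.wave,
                    "gp_id": self.gp_id,
                    "indicator_id": f.indicator_id,
                    "own_pct": f.own_pct,
                    "regional_median": f.regional_median,
                    "acceptable_pct": f.acceptable_pct,
                    "ideal_pct": f.ideal_pct,
                    "standard_class": f.standard_class.value,
                    "peer_pcts": ";".join(f"{v:.1f}" for v in f.peer_pcts),
                }
                for f in self.feedback
            ]
        )

    def to_text(self) -> str:
        """Plain-text rendering of the written feedback."""
        lines = [
            f"Quality-indicator feedback — practice {self.gp_id}, wave {self.wave}",
            "(peer values are anonymised and shuffled)",
            "",
        ]
        for f in self.feedback:
            own = "n/a" if f.own_pct is None else f"{f.own_pct:.1f}%"
            med = "n/a" if f.regional_median is None else f"{f.regional_median:.1f}%"
            std = (
                "n/a"
                if f.acceptable_pct is None
                else f"{f.acceptable_pct:g}/{f.ideal_pct:g}%"
            )
            peers = ", ".join(f"{v:.1f}" for v in f.peer_pcts) or "n/a"
            lines.append(
                f"{f.indicator_id}: you {own} | region median {med} | "
                f"standards {std} | status {f.standard_class.value} | "
                f"peers {peers}"
            )
        return "\n".join(lines)


def build_reports(
    table: AchievementTable,
    registry: IndicatorRegistry,
    seed: int,
    quantile_method: str = "linear",
) -> list[BenchmarkReport]:
    """One benchmark report per practice, peer order seeded-shuffled."""
    summary = regional_summary(table, quantile_method=quantile_method)
    rng = np.random.default_rng(seed)
    reports = []
    for gp in table.gp_ids:
        feedback = []
        for d in registry:
            ind = d.indicator_id
            values = table.values_for(ind)
            own = values.get(gp)
            peers = np.array([v for g, v in values.items() if g != gp], dtype=float)
            rng.shuffle(peers)
            med = summary.loc[ind, "median"]
            feedback.append(
                IndicatorFeedback(
                    indicator_id=ind,
                    own_pct=own,
                    peer_pcts=tuple(float(v) for v in peers),
                    regional_median=None if np.isnan(med) else float(med),
                    acceptable_pct=d.acceptable_pct,
                    ideal_pct=d.ideal_pct,
                    standard_class=classify_standard(
                        own, d.acceptable_pct, d.ideal_pct
                    ),
                )
            )
        reports.append(
            BenchmarkReport(gp_id=gp, wave=table.wave, feedback=tuple(feedback))
        )
    return reports
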