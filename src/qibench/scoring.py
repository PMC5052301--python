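"""Median-anchored quality score: cutoff derivation and point assignment.

Each scored indicator earns 0–5 points per practice.  The point bins are
anchored at the cohort's baseline median achievement: the median minus
10 percentage points, rounded to the 5 % grid, is the minimum to earn
one point; each further 5 % earns one more point, up to five.  A floor
protects low-performing indicators: when the baseline median is below
20 %, the one-point minimum is fixed at 10 %.  Summing over the 35
scored indicators gives a practice quality score between 0 and 175.

The grid rounding matches the published cutoff spreadsheet, whose single
observable half-way case rounds down (median 57.5 → one-point bound 45).
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .engine import AchievementTable
from .registry import IndicatorRegistry

__all__ = [
    "CutoffRow",
    "CutoffTable",
    "ScoreTable",
    "LOW_MEDIAN_THRESHOLD",
    "LOW_MEDIAN_FLOOR",
    "BIN_WIDTH",
    "MEDIAN_OFFSET",
    "MAX_POINTS",
    "round_to_grid",
    "derive_cutoffs",
    "assign_points",
    "score_practices",
    "baseline_medians",
    "reference_baseline_medians",
]

#: Medians below this get the fixed one-point floor instead of median-10.
LOW_MEDIAN_THRESHOLD = 20.0
#: The fixed one-point minimum for low-median indicators, percent.
LOW_MEDIAN_FLOOR = 10.0
#: Width of each point bin, percentage points.
BIN_WIDTH = 5.0
#: Offset below the median for the one-point minimum, percentage points.
MEDIAN_OFFSET = 10.0
#: Maximum points per indicator.
MAX_POINTS = 5

_HALF = BIN_WIDTH / 2.0
_TIE_TOL = 1e-9


def round_to_grid(x: float) -> float:
    """Round a percentage to the nearest multiple of 5, half-way ties down.

    The tie direction is pinned by the published spreadsheet (47.5 → 45).
    """
    if x < 0:
        raise ValueError(f"cannot grid-round negative percentage {x}")
    base = BIN_WIDTH * math.floor(x / BIN_WIDTH)
    rem = x - base
    if rem > _HALF + _TIE_TOL:
        return base + BIN_WIDTH
    return base


@dataclasses.dataclass(frozen=True)
class CutoffRow:
    """Point-bin boundaries for one scored indicator."""

    indicator_id: str
    baseline_median_pct: float
    zero_point_upper: float  # achievement below this earns 0 points

    def lower_bound(self, points: int) -> float:
        """Lower bound of the bin worth ``points`` (1..5); the 5-bin is open."""
        if not 1 <= points <= MAX_POINTS:
            raise ValueError(f"points must be 1..{MAX_POINTS}")
        return self.zero_point_upper + BIN_WIDTH * (points - 1)

    @property
    def bin_lower_bounds(self) -> tuple[float, ...]:
        return tuple(self.lower_bound(k) for k in range(1, MAX_POINTS + 1))


@dataclasses.dataclass(frozen=True)
class CutoffTable:
    """Per-indicator point bins (the cutoff spreadsheet object)."""

    rows: dict[str, CutoffRow]

    def __getitem__(self, indicator_id: str) -> CutoffRow:
        return self.rows[indicator_id]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Spreadsheet layout: median plus the six bin descriptions."""
        records = []
        for row in self.rows.values():
            rec: dict[str, object] = {
                "indicator_id": row.indicator_id,
                "median_pct": row.baseline_median_pct,
                "points_0": f"<{row.zero_point_upper:g}",
            }
            for k in range(1, MAX_POINTS):
                lo = row.lower_bound(k)
                rec[f"points_{k}"] = f"{lo:.1f}-{lo + BIN_WIDTH - 0.1:.1f}"
            rec[f"points_{MAX_POINTS}"] = f">={row.lower_bound(MAX_POINTS):g}"
            records.append(rec)
        return pd.DataFrame(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def derive_cutoffs(
    baseline_medians: Mapping[str, float],
    registry: IndicatorRegistry | None = None,
) -> CutoffTable:
    """Derive point bins from baseline median achievements.

    ``baseline_medians`` maps indicator_id → median percent for every
    scored indicator.  When a registry is given, a missing or surplus
    id set raises ``ValueError`` naming the offending ids.
    """
    if registry is not None:
        wanted = {d.indicator_id for d in registry.scored}
        got = set(baseline_medians)
        if wanted - got:
            raise ValueError(
                f"baseline medians missing for indicators: {sorted(wanted - got)}"
            )
        ids = [d.indicator_id for d in registry.scored]
    else:
        ids = list(baseline_medians)
    rows = {}
    for ind in ids:
        median = float(baseline_medians[ind])
        if not 0.0 <= median <= 100.0:
            raise ValueError(f"{ind}: median {median} outside [0, 100]")
        if median < LOW_MEDIAN_THRESHOLD:
            zero_upper = LOW_MEDIAN_FLOOR
        else:
            zero_upper = round_to_grid(median - MEDIAN_OFFSET)
        rows[ind] = CutoffRow(
            indicator_id=ind,
            baseline_median_pct=median,
            zero_point_upper=zero_upper,
        )
    return CutoffTable(rows=rows)


def assign_points(achievement_pct: float, row: CutoffRow) -> int:
    """Points (0–5) for one achievement percentage.

    Bin membership is [lower, lower + 5) in exact arithmetic; the
    printed "–x9.9" upper edges are display formatting of one-decimal
    data, so e.g. 49.95 earns the higher bin.
    """
    if not 0.0 <= achievement_pct <= 100.0:
        raise ValueError(f"achievement {achievement_pct} outside [0, 100]")
    if achievement_pct < row.zero_point_upper:
        return 0
    points = 1 + math.floor(
        (achievement_pct - row.zero_point_upper) / BIN_WIDTH + _TIE_TOL
    )
    return min(points, MAX_POINTS)


@dataclasses.dataclass
class ScoreTable:
    """Per-practice quality scores for one wave.

    ``total_scores[gp]`` is None for practices with no scoreable
    indicator (e.g. prevalence-only record systems).
    """

    wave: str
    total_scores: dict[str, Optional[int]]
    points: dict[tuple[str, str], Optional[int]]  # (gp_id, indicator_id)
    n_scoreable: dict[str, int]

    def is_calculable(self, gp_id: str) -> bool:
        return self.total_scores[gp_id] is not None

    @property
    def scores(self) -> dict[str, int]:
        """Calculable scores only, keyed by gp_id."""
        return {g: s for g, s in self.total_scores.items() if s is not None}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gp, total in self.total_scores.items():
            rows.append(
                {
                    "wave": self.wave,
                    "gp_id": gp,
                    "score": total,
                    "n_scoreable": self.n_scoreable[gp],
                    "calculable": total is not None,
                }
            )
        return pd.DataFrame(rows)

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"wave": self.wave, "gp_id": gp, "indicator_id": ind, "points": pts}
                for (gp, ind), pts in self.points.items()
            ]
        )


def score_practices(
    table: AchievementTable,
    cutoffs: CutoffTable,
    registry: IndicatorRegistry,
    missing_policy: str = "zero",
) -> ScoreTable:
    """Sum indicator points into per-practice quality scores.

    Missing cells contribute 0 points under the default ``zero`` policy
    (practices with excluded indicators still get a score on the common
    0–175 scale); ``drop`` omits them from the sum identically but
    records them as None either way.  A practice with no scoreable cell
    at all — e.g. one whose record system exports only prevalences — is
    flagged not calculable (score None).
    """
    if missing_policy not in {"zero", "drop"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    scored_ids = [d.indicator_id for d in registry.scored]
    missing_cutoffs = [i for i in scored_ids if i not in cutoffs.rows]
    if missing_cutoffs:
        raise ValueError(f"no cutoff row for indicators: {missing_cutoffs}")
    totals: dict[str, Optional[int]] = {}
    points: dict[tuple[str, str], Optional[int]] = {}
    n_scoreable: dict[str, int] = {}
    for gp in table.gp_ids:
        n = 0
        total = 0
        for ind in scored_ids:
            cell = table.cell(gp, ind)
            if cell.is_missing:
                points[(gp, ind)] = None
            else:
                pts = assign_points(cell.pct, cutoffs[ind])
                points[(gp, ind)] = pts
                total += pts
                n += 1
        n_scoreable[gp] = n
        totals[gp] = total if n > 0 else None
    return ScoreTable(
        wave=table.wave, total_scores=totals, points=points, n_scoreable=n_scoreable
    )


def baseline_medians(
    table: AchievementTable, registry: IndicatorRegistry
) -> dict[str, float]:
    """Median achievement per scored indicator over non-missing practices.

    This is the input to ``derive_cutoffs`` when anchoring the score to
    a cohort's own baseline wave.
    """
    medians = {}
    for d in registry.scored:
        values = list(table.values_for(d.indicator_id).values())
        if not values:
            raise ValueError(f"{d.indicator_id}: no non-missing baseline values")
        medians[d.indicator_id] = float(np.median(values))
    return medians


def reference_baseline_medians() -> dict[str, float]:
    """The published baseline medians shipped with the package.

    These are the 35 per-indicator baseline medians of the Austrian
    audit cohort from which the reference cutoff spreadsheet was built.
    """
    with resources.files("qibench.data").joinpath("baseline_medians.csv").open() as fh:
        frame = pd.read_csv(fh)
    return dict(zip(frame["indicator_id"], frame["median_pct"].astype(float)))
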