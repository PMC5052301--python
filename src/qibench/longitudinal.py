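"""Paired pre-post analysis across extraction waves.

Practices are the unit of analysis.  For every indicator (and for the
total quality score) the per-wave distribution is summarised as median,
first and third quartile, and each wave pair is compared with a paired
Wilcoxon signed-rank test on the practices present in both waves.
Achievement percentages are typically skewed across practices, so the
nonparametric paired test is the primary analysis; a Kolmogorov–Smirnov
normality screen of the paired differences is computed as an advisory
only and never switches the test.

Significance is read at α = 0.05, two-sided, per test.  No familywise
correction gates the direction flags (each indicator is reported on its
own), but a Holm-adjusted p-value column is emitted alongside for
transparency about multiplicity.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .engine import AchievementTable
from .scoring import ScoreTable

__all__ = [
    "ALPHA",
    "EXACT_N_MAX",
    "WilcoxonResult",
    "LongitudinalResult",
    "paired_wilcoxon",
    "normality_check",
    "longitudinal_table",
]

#: Two-sided significance level.
ALPHA = 0.05
#: Largest paired-sample size for which the exact null distribution is used.
EXACT_N_MAX = 25
#: Score pseudo-indicator id used in longitudinal output rows.
SCORE_ROW_ID = "quality_score"


@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    statistic: Optional[float]
    p_value: Optional[float]
    n_used: int  # nonzero paired differences
    n_pairs: int  # complete pairs before zero removal
    degenerate: bool = False  # all paired differences zero

    @property
    def available(self) -> bool:
        return self.p_value is not None


def paired_wilcoxon(
    a: Mapping[str, float] | Sequence[float],
    b: Mapping[str, float] | Sequence[float],
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    ``a`` and ``b`` are per-practice values for the two waves, either as
    mappings keyed by gp_id (paired on the common keys) or as equal-length
    sequences (paired positionally).  Practices missing either value are
    dropped.  Zero differences are excluded (classic signed-rank
    reduction); the exact null distribution is used for n ≤ 25 when the
    absolute differences are untied, otherwise the normal approximation
    with tie correction.

    All-zero differences give a degenerate result with p = 1; no
    complete pair at all gives an unavailable result.
    """
    if isinstance(a, Mapping) != isinstance(b, Mapping):
        raise TypeError("a and b must both be mappings or both sequences")
    if isinstance(a, Mapping):
        keys = sorted(set(a) & set(b))
        x = np.array([a[k] for k in keys], dtype=float)
        y = np.array([b[k] for k in keys], dtype=float)
    else:
        if len(a) != len(b):
            raise ValueError("positional pairing requires equal-length sequences")
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n_pairs = len(x)
    if n_pairs == 0:
        return WilcoxonResult(None, None, 0, 0)
    diffs = y - x
    nonzero = diffs[diffs != 0.0]
    n_used = len(nonzero)
    if n_used == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_pairs, degenerate=True)
    ties = len(np.unique(np.abs(nonzero))) < n_used
    method = "exact" if (n_used <= EXACT_N_MAX and not ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            nonzero, zero_method="wilcox", alternative="two-sided", method=method
        )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=n_used,
        n_pairs=n_pairs,
    )


def normality_check(values: Sequence[float]) -> Optional[float]:
    """One-sample Kolmogorov–Smirnov p-value against a fitted normal.

    Mean and standard deviation are estimated from the sample (no
    small-sample correction).  Advisory only.  Returns None for n < 3 or
    a constant sample.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        return None
    sd = x.std(ddof=1)
    if sd == 0.0:
        return None
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def _direction(
    a: Mapping[str, float], b: Mapping[str, float], result: WilcoxonResult
) -> str:
    if not result.available or result.p_value >= ALPHA or result.degenerate:
        return "none"
    keys = sorted(set(a) & set(b))
    diffs = np.array([b[k] - a[k] for k in keys], dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    return "increase" if np.median(diffs[diffs != 0.0]) > 0 else "decrease"


def _wave_pairs(waves: Sequence[str]) -> list[tuple[str, str]]:
    pairs = [(waves[i], waves[i + 1]) for i in range(len(waves) - 1)]
    if len(waves) > 2:
        pairs.append((waves[0], waves[-1]))
    return pairs


@dataclasses.dataclass
class LongitudinalResult:
    """Per-indicator wave summaries and pairwise test results.

    ``summaries`` has one row per (row_id, wave) with median/q1/q3/n;
    ``tests`` one row per (row_id, wave pair) with the Wilcoxon result,
    Holm-adjusted p (across indicators within the wave pair), the
    advisory normality p of the paired differences and the direction
    flag.  ``row_id`` runs over indicator ids plus the total-score row.
    """

    waves: tuple[str, ...]
    summaries: pd.DataFrame
    tests: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: per-wave median/Q1/Q3 columns plus per-pair p-values."""
        wide = self.summaries.pivot(
            index="row_id", columns="wave", values=["median", "q1", "q3"]
        )
        wide.columns = [f"{stat}_{wave}" for stat, wave in wide.columns]
        pv = self.tests.pivot(index="row_id", columns="pair", values="p_value")
        pv.columns = [f"p_{c}" for c in pv.columns]
        out = wide.join(pv).reset_index()
        order = {r: i for i, r in enumerate(dict.fromkeys(self.summaries["row_id"]))}
        return out.sort_values("row_id", key=lambda s: s.map(order)).reset_index(
            drop=True
        )


def longitudinal_table(
    tables: Sequence[AchievementTable],
    scores: Sequence[ScoreTable] | None = None,
) -> LongitudinalResult:
    """Build the full longitudinal analysis across ≥ 2 waves.

    ``tables`` are per-wave achievement tables (one per wave, ordered);
    ``scores`` optionally the matching per-wave score tables, adding a
    total-score row.  Wave pairs are all consecutive pairs plus
    (first, last) when more than two waves are given.  Practices with a
    missing value in either wave of a pair are dropped from that pair
    (pairwise-complete pairing).
    """
    if len(tables) < 2:
        raise ValueError("longitudinal analysis needs at least two waves")
    waves = [t.wave for t in tables]
    if len(set(waves)) != len(waves):
        raise ValueError("duplicate wave labels")
    if scores is not None and [s.wave for s in scores] != waves:
        raise ValueError("score tables must match achievement-table waves")

    indicator_ids = tables[0].indicator_ids
    rows: list[tuple[str, dict[str, dict[str, float]]]] = []
    for ind in indicator_ids:
        rows.append((ind, {t.wave: t.values_for(ind) for t in tables}))
    if scores is not None:
        rows.append(
            (
                SCORE_ROW_ID,
                {s.wave: {g: float(v) for g, v in s.scores.items()} for s in scores},
            )
        )

    summary_rows = []
    test_rows = []
    for row_id, by_wave in rows:
        for wave in waves:
            values = list(by_wave[wave].values())
            if values:
                q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
                summary_rows.append(
                    {"row_id": row_id, "wave": wave, "median": med, "q1": q1,
                     "q3": q3, "n": len(values)}
                )
            else:
                summary_rows.append(
                    {"row_id": row_id, "wave": wave, "median": np.nan, "q1": np.nan,
                     "q3": np.nan, "n": 0}
                )
        for wa, wb in _wave_pairs(waves):
            a, b = by_wave[wa], by_wave[wb]
            res = paired_wilcoxon(a, b)
            keys = sorted(set(a) & set(b))
            diffs = [b[k] - a[k] for k in keys]
            test_rows.append(
                {
                    "row_id": row_id,
                    "pair": f"{wa}-{wb}",
                    "n_pairs": res.n_pairs,
                    "n_used": res.n_used,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "degenerate": res.degenerate,
                    "normality_p": normality_check(diffs),
                    "direction": _direction(a, b, res),
                }
            )
    tests = pd.DataFrame(test_rows)
    tests["p_holm"] = np.nan
    for pair in tests["pair"].unique():
        mask = (tests["pair"] == pair) & tests["p_value"].notna()
        if mask.sum() > 0:
            tests.loc[mask, "p_holm"] = multipletests(
                tests.loc[mask, "p_value"], method="holm"
            )[1]
    return LongitudinalResult(
        waves=tuple(waves), summaries=pd.DataFrame(summary_rows), tests=tests
    )
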