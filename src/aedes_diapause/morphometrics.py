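"""Egg morphometry: triplicate summaries, spheroid volume, seasonal
regressions, cutoff-based grouping and rank tests.

An egg is treated as a prolate spheroid, so its volume from length L and
width W (both in um) is V = (pi/6) L W^2, reported in 1e-3 mm^3 (the um^3
value divided by 1e6).  Seasonal trends are fitted by ordinary least
squares on weekly median values, matching how boxplot-per-week data are
usually summarised; a per-egg fit is available through ``unit="egg"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .core import EggRecord

__all__ = [
    "EggMorphometry",
    "RegressionFit",
    "GroupAssignment",
    "RankTestResult",
    "egg_volume",
    "summarize_reps",
    "morphometry_frame",
    "weekly_medians",
    "seasonal_regression",
    "split_season",
    "assign_groups",
    "wilcoxon_one_tailed",
    "kruskal_wallis",
]

logger = logging.getLogger(__name__)

#: largest pooled sample size for which the Wilcoxon p-value is computed
#: by exact enumeration of labelings
EXACT_ENUMERATION_MAX_N = 12


def egg_volume(length_um: float, width_um: float) -> float:
    """Prolate-spheroid egg volume in 1e-3 mm^3: (pi/6) L W^2 / 1e6."""
    if length_um <= 0 or width_um <= 0:
        raise ValueError("length and width must be positive")
    return math.pi / 6.0 * length_um * width_um**2 / 1e6


@dataclass(frozen=True)
class EggMorphometry:
    egg_id: str
    length_um: float
    width_um: float
    volume_e3mm3: float


def summarize_reps(record: EggRecord) -> EggMorphometry | None:
    """Mean of the three reps per axis, then the spheroid volume.

    Returns ``None`` (with a log entry) when the record carries no
    morphometry.
    """
    if not record.has_morphometry:
        logger.debug("egg %s has no morphometry; skipped", record.egg_id)
        return None
    length = sum(record.length_reps_um) / 3.0
    width = sum(record.width_reps_um) / 3.0
    return EggMorphometry(record.egg_id, length, width, egg_volume(length, width))


def morphometry_frame(records: Iterable[EggRecord]) -> pd.DataFrame:
    """Per-egg morphometry table (egg_id, year, week, status, L, W, V)."""
    rows = []
    for r in records:
        m = summarize_reps(r)
        if m is None:
            continue
        rows.append(
            {
                "egg_id": r.egg_id,
                "iso_year": r.iso_year,
                "iso_week": r.iso_week,
                "status": r.status.value,
                "length_um": m.length_um,
                "width_um": m.width_um,
                "volume_e3mm3": m.volume_e3mm3,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "egg_id", "iso_year", "iso_week", "status",
            "length_um", "width_um", "volume_e3mm3",
        ],
    )


def weekly_medians(frame: pd.DataFrame, response: str) -> list[tuple[int, float]]:
    """(week, median value) pairs for one response column, week-sorted."""
    g = frame.groupby("iso_week")[response].median()
    return [(int(w), float(v)) for w, v in g.sort_index().items()]


@dataclass(frozen=True)
class RegressionFit:
    response_name: str
    slope: float
    intercept: float
    slope_se: float
    r_squared_adj: float
    p_value: float
    weeks_used: tuple[int, ...]
    n: int


def seasonal_regression(
    weekly_values: Sequence[tuple[float, float]],
    week_range: tuple[int, int] | None = None,
    response_name: str = "value",
) -> RegressionFit:
    """OLS of a weekly series on week number: value = b0 + b1 * week.

    ``weekly_values`` is a (week, value) sequence — typically weekly
    medians.  Reports the slope with its standard error, the adjusted R^2
    and the slope's two-sided p-value.
    """
    pts = [
        (w, v)
        for w, v in weekly_values
        if week_range is None or week_range[0] <= w <= week_range[1]
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 weekly points in range, got {len(pts)}")
    weeks = np.asarray([p[0] for p in pts], dtype=float)
    vals = np.asarray([p[1] for p in pts], dtype=float)
    if np.ptp(weeks) == 0:
        raise ValueError("zero variance in week")
    X = sm.add_constant(weeks)
    fit = sm.OLS(vals, X).fit()
    return RegressionFit(
        response_name=response_name,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        r_squared_adj=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]),
        weeks_used=tuple(int(w) for w in weeks),
        n=len(pts),
    )


def split_season(
    weekly_values: Sequence[tuple[float, float]],
    early_range: tuple[int, int],
    late_range: tuple[int, int],
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Partition a weekly series into the early and late seasonal regimes.

    Egg size follows two regimes over the season (an early plateau from the
    overwintered generation, then a late rise), so trend fits are done per
    regime.  Ranges are inclusive and must not overlap; weeks in neither
    range are dropped.
    """
    if early_range[0] <= late_range[1] and late_range[0] <= early_range[1]:
        raise ValueError(f"overlapping ranges {early_range} and {late_range}")
    early = [(w, v) for w, v in weekly_values if early_range[0] <= w <= early_range[1]]
    late = [(w, v) for w, v in weekly_values if late_range[0] <= w <= late_range[1]]
    if not early:
        logger.warning("no weeks in early range %s; late-only analysis", early_range)
    return early, late


@dataclass(frozen=True)
class GroupAssignment:
    """ND / M / D labels around the 50% cutoff week n.

    M spans weeks n-1..n+1 (the mixed window around the crossing), ND is
    everything earlier, D everything later.  Only observed weeks are
    labelled.
    """

    cutoff_week: int
    labels: Mapping[int, str]

    def weeks(self, label: str) -> list[int]:
        return sorted(w for w, l in self.labels.items() if l == label)


def assign_groups(cutoff_week: int, observed_weeks: Iterable[int]) -> GroupAssignment:
    labels: dict[int, str] = {}
    for w in observed_weeks:
        if w < cutoff_week - 1:
            labels[w] = "ND"
        elif w <= cutoff_week + 1:
            labels[w] = "M"
        else:
            labels[w] = "D"
    return GroupAssignment(cutoff_week, labels)


@dataclass(frozen=True)
class RankTestResult:
    test_name: str
    statistic: float
    p_value: float
    effect_pct: float | None = None
    method: str = ""
    degenerate: bool = False


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y, from average ranks of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[: len(x)].sum()
    return rx - len(x) * (len(x) + 1) / 2.0


def wilcoxon_one_tailed(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
) -> RankTestResult:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) test of x against y.

    The statistic is the Mann-Whitney U of ``x`` computed with average
    ranks for ties.  For pooled samples of at most
    ``EXACT_ENUMERATION_MAX_N`` the p-value is exact, by enumerating every
    assignment of the pooled values to the two groups; beyond that the
    tie-corrected normal approximation (with continuity correction) is
    used.  ``effect_pct`` is the percent difference of group means,
    100 * (mean(x) - mean(y)) / mean(y).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _rank_sum_u(x, y)
    effect = float(100.0 * (x.mean() - y.mean()) / y.mean()) if y.mean() != 0 else None

    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return RankTestResult(
            "wilcoxon_one_tailed", u_obs, 1.0, 0.0, "degenerate", degenerate=True
        )

    n = len(pooled)
    if n <= EXACT_ENUMERATION_MAX_N:
        ranks = sps.rankdata(pooled)
        nx = len(x)
        offset = nx * (nx + 1) / 2.0
        us = np.array(
            [ranks[list(idx)].sum() - offset for idx in combinations(range(n), nx)]
        )
        eps = 1e-9
        if alternative == "greater":
            p = float(np.mean(us >= u_obs - eps))
        else:
            p = float(np.mean(us <= u_obs + eps))
        method = "exact enumeration"
    else:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
        method = "normal approximation, tie-corrected"
    return RankTestResult("wilcoxon_one_tailed", float(u_obs), p, effect, method)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis H across two or more groups (tie-corrected), with the
    chi-square p-value on k-1 degrees of freedom.

    Used to check that weeks pooled into one ND/M/D group behave as a
    homogeneous group.  All-identical pooled values give H = 0, p = 1
    (degenerate), rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return RankTestResult("kruskal_wallis", 0.0, 1.0, None, "degenerate", True)
    h, p = sps.kruskal(*arrays)
    return RankTestResult("kruskal_wallis", float(h), float(p), None, "chi-square")
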