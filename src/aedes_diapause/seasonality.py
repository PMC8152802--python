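"""Seasonality: weekly weather aggregation, the egg-laying temperature
threshold, Spearman associations and egg-abundance series.

The activity threshold is a descriptive statistic of the egg-positive
season: the mean of (i) the lowest weekly-average daily-minimum
temperature and (ii) the lowest weekly-average daily-maximum temperature
observed over weeks with eggs.  It estimates the temperature floor below
which oviposition is no longer observed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .core import EggRecord, MeteoDay, MeteoWeek, Site
from .photoperiod import iso_week_of

__all__ = [
    "AbundanceBin",
    "AbundanceSeries",
    "CorrelationResult",
    "weekly_meteo",
    "activity_threshold",
    "spearman",
    "abundance_series",
]

#: below this sample size the Spearman p-value is computed by exact
#: permutation instead of the t approximation
SPEARMAN_EXACT_MAX_N = 9


def weekly_meteo(days: Iterable[MeteoDay]) -> list[MeteoWeek]:
    """Aggregate a daily station record into ISO-week summaries.

    Produces the eight temperature aggregates plus average/cumulative
    sunshine and rainfall.  Weeks with fewer than 7 days are aggregated
    over the available days and flagged via ``MeteoWeek.partial``.
    """
    rows = [
        {
            "iso_year": iso_week_of(d.date)[0],
            "iso_week": iso_week_of(d.date)[1],
            "tmin": d.tmin_C,
            "tmax": d.tmax_C,
            "sun": d.sunshine_min,
            "rain": d.rainfall_mm,
        }
        for d in days
    ]
    if not rows:
        return []
    df = pd.DataFrame(rows)
    out = []
    for (y, w), g in df.groupby(["iso_year", "iso_week"], sort=True):
        out.append(
            MeteoWeek(
                iso_year=int(y),
                iso_week=int(w),
                avTmin=float(g["tmin"].mean()),
                avTmax=float(g["tmax"].mean()),
                minTmin=float(g["tmin"].min()),
                minTmax=float(g["tmax"].min()),
                maxTmin=float(g["tmin"].max()),
                maxTmax=float(g["tmax"].max()),
                avSun=float(g["sun"].mean()),
                cumulSun=float(g["sun"].sum()),
                avRain=float(g["rain"].mean()),
                cumulRain=float(g["rain"].sum()),
                n_days=int(len(g)),
            )
        )
    return out


def activity_threshold(
    weeks_with_eggs: Iterable[tuple[int, int]],
    meteo: Sequence[MeteoWeek],
) -> float:
    """Mean of the seasonal minima of avTmin and avTmax over egg weeks (degC)."""
    egg_weeks = set(weeks_with_eggs)
    if not egg_weeks:
        raise ValueError("no egg-positive weeks")
    sel = [m for m in meteo if (m.iso_year, m.iso_week) in egg_weeks]
    if not sel:
        raise ValueError("no overlap between egg weeks and meteo weeks")
    min_avtmin = min(m.avTmin for m in sel)
    min_avtmax = min(m.avTmax for m in sel)
    return (min_avtmin + min_avtmax) / 2.0


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_value: float
    n: int
    method: str = ""
    degenerate: bool = False


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    var_x: str = "x",
    var_y: str = "y",
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks.  The p-value uses the
    t approximation on n - 2 degrees of freedom for n >= 10 and an exact
    permutation distribution below that (weekly series are short, where
    the approximation is poorest).  Zero variance in either variable gives
    a flagged NaN result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            var_x, var_y, float("nan"), float("nan"), n, "degenerate", True
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > SPEARMAN_EXACT_MAX_N:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
        method = "t approximation"
    else:
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        pv = perms - ry.mean()
        rhos = (pv @ rx_c) / math.sqrt((rx_c @ rx_c) * float((pv[0] @ pv[0])))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact permutation"
    return CorrelationResult(var_x, var_y, rho, p, n, method)


@dataclass(frozen=True)
class AbundanceBin:
    iso_year: int
    start_week: int
    egg_count: int


@dataclass(frozen=True)
class AbundanceSeries:
    site: str
    bin_width: int
    bins: tuple[AbundanceBin, ...]
    season_total: Mapping[int, int]
    mean_per_bin: Mapping[int, float]
    sd_per_bin: Mapping[int, float]


def abundance_series(
    counts: pd.DataFrame | Iterable[EggRecord],
    bin_width: int = 2,
    site: str = "",
) -> AbundanceSeries:
    """Binned egg-abundance series with per-season totals and mean +/- SD.

    Accepts either per-egg records or a table with columns
    (iso_year, iso_week, count).  Bins of ``bin_width`` weeks start at the
    first observed week of each season; binning conserves totals for any
    width.  SD is the sample SD (ddof=1) over bins, 0 for a single bin.
    """
    if bin_width not in (1, 2):
        raise ValueError("bin_width must be 1 or 2")
    if isinstance(counts, pd.DataFrame):
        df = counts[["iso_year", "iso_week", "count"]].copy()
    else:
        rows = [{"iso_year": r.iso_year, "iso_week": r.iso_week, "count": 1}
                for r in counts]
        if not rows:
            raise ValueError("no egg counts")
        df = pd.DataFrame(rows)
    bins: list[AbundanceBin] = []
    totals: dict[int, int] = {}
    means: dict[int, float] = {}
    sds: dict[int, float] = {}
    for y, g in df.groupby("iso_year", sort=True):
        start = int(g["iso_week"].min())
        b = g.assign(bin=start + bin_width * ((g["iso_week"] - start) // bin_width))
        agg = b.groupby("bin")["count"].sum().sort_index()
        for wk, c in agg.items():
            bins.append(AbundanceBin(int(y), int(wk), int(c)))
        vals = agg.to_numpy(dtype=float)
        totals[int(y)] = int(vals.sum())
        means[int(y)] = float(vals.mean())
        sds[int(y)] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return AbundanceSeries(site, bin_width, tuple(bins), totals, means, sds)
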