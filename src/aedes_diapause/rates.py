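"""Egg-status rates, the weekly diapause-incidence series, the sustained
50% cutoff and the maternal critical photoperiod (CPP).

With H hatched, E embryonated-unhatched, P partially embryonated and U
unfertilised eggs in a cohort, the four rates are

    hatching success (%)   = 100 * H / (H + E)
    diapause incidence (%) = 100 * E / (H + E)  = 100 - hatching success
    viability (%)          = 100 * (H + E) / (H + E + P + U)
    mortality (%)          = 100 * (P + U) / (H + E + P + U)

Viable eggs are H + E; incidence is defined over viable eggs only.  The
CPP is the day length sensed by ovipositing females in the week their
eggs reach 50% diapause incidence, i.e. the weekly photoperiod at
``cutoff_week - delay_weeks`` where the maternal delay accounts for the
lag between photoperiod perception and egg collection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import datetime as dt

from .core import CohortCounts, EggRecord, Site, tally_cohorts
from .photoperiod import (
    DEFAULT_ZENITH_DEG,
    iso_week_of,
    minutes_to_hhmm,
    weekly_photoperiod,
)

__all__ = [
    "NoViableEggsError",
    "RateSummary",
    "CutoffResult",
    "CppResult",
    "rates_from_counts",
    "weekly_incidence",
    "detect_cutoff",
    "compute_cpp",
    "average_cpp",
    "mortality_series",
    "MortalitySummary",
]

logger = logging.getLogger(__name__)

#: Cohorts smaller than this are dropped from weekly series (a field week
#: with only 5 eggs is too small to estimate an incidence from).
DEFAULT_MIN_N = 6


class NoViableEggsError(ValueError):
    """Hatching success / diapause incidence are undefined when H + E = 0."""


@dataclass(frozen=True)
class RateSummary:
    iso_year: int
    iso_week: int
    n_tested: int
    n_viable: int
    hatching_success_pct: float
    viability_pct: float
    mortality_pct: float
    diapause_incidence_pct: float


@dataclass(frozen=True)
class CutoffResult:
    """The week at which diapause incidence first crosses a threshold and
    stays there.  ``cutoff_week is None`` means no sustained crossing was
    observed that season (a result, not an error)."""

    iso_year: int
    cutoff_week: int | None
    incidence_at_cutoff_pct: float | None
    threshold_pct: float
    weeks_used: tuple[int, ...]

    @property
    def found(self) -> bool:
        return self.cutoff_week is not None


@dataclass(frozen=True)
class CppResult:
    iso_year: int
    cutoff_week: int
    delay_weeks: int
    maternal_iso_year: int
    maternal_iso_week: int
    cpp_min: float

    @property
    def cpp_hhmm(self) -> str:
        return minutes_to_hhmm(self.cpp_min)


def rates_from_counts(c: CohortCounts) -> RateSummary:
    """The four rate formulas on one cohort's tallies.

    Raises :class:`NoViableEggsError` when H + E = 0: a cohort with no
    viable eggs has no defined hatching success or diapause incidence
    (reporting 0 would fabricate a measurement).
    """
    if c.total_tested < 1:
        raise NoViableEggsError(
            f"cohort {c.iso_year}-W{c.iso_week:02d}: no tested eggs"
        )
    if c.viable < 1:
        raise NoViableEggsError(
            f"cohort {c.iso_year}-W{c.iso_week:02d}: no viable eggs "
            "(hatching success and diapause incidence undefined)"
        )
    viable = c.H + c.E
    total = c.total_tested
    return RateSummary(
        iso_year=c.iso_year,
        iso_week=c.iso_week,
        n_tested=total,
        n_viable=viable,
        hatching_success_pct=100.0 * c.H / viable,
        viability_pct=100.0 * viable / total,
        mortality_pct=100.0 * (c.P + c.U) / total,
        diapause_incidence_pct=100.0 * c.E / viable,
    )


def weekly_incidence(
    records: Iterable[EggRecord],
    min_n: int = DEFAULT_MIN_N,
    week_range: tuple[int, int] | None = None,
) -> list[RateSummary]:
    """Weekly rate series, pooled over traps, ordered by (year, week).

    Cohorts with fewer than ``min_n`` tested eggs are omitted (and logged),
    as are cohorts with no viable egg.  ``week_range`` optionally restricts
    the series to an analysis window (inclusive).
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    out: list[RateSummary] = []
    for c in tally_cohorts(records, group_by="week"):
        if week_range is not None and not week_range[0] <= c.iso_week <= week_range[1]:
            continue
        if c.total_tested < min_n:
            logger.info(
                "omitting %s-W%02d: n=%d < min_n=%d",
                c.iso_year, c.iso_week, c.total_tested, min_n,
            )
            continue
        if c.viable < 1:
            logger.info(
                "omitting %s-W%02d: no viable eggs", c.iso_year, c.iso_week
            )
            continue
        out.append(rates_from_counts(c))
    return out


def series_from_binomial_counts(
    counts, iso_year: int = 2019
) -> list[RateSummary]:
    """Rate series from a weekly (iso_week, n, n_diapause) table of viable
    eggs — the shape produced by lightweight incidence simulations."""
    out = []
    for row in counts.to_dict("records"):
        c = CohortCounts(
            iso_year=iso_year,
            iso_week=int(row["iso_week"]),
            H=int(row["n"] - row["n_diapause"]),
            E=int(row["n_diapause"]),
        )
        out.append(rates_from_counts(c))
    return out


def detect_cutoff(
    series: Sequence[RateSummary],
    threshold_pct: float = 50.0,
    sustain: int = 2,
) -> CutoffResult:
    """Earliest week at or above ``threshold_pct`` whose next ``sustain``
    observed weeks (or all remaining, if fewer) also stay at or above it.

    The sustain rule protects against a single noisy week crossing the
    threshold early in an otherwise sub-threshold run.  Exact equality
    counts as crossing.  The series must come from a single season.
    """
    if not series:
        raise ValueError("empty incidence series")
    years = {s.iso_year for s in series}
    if len(years) > 1:
        raise ValueError(f"series spans several seasons: {sorted(years)}")
    ordered = sorted(series, key=lambda s: s.iso_week)
    weeks = tuple(s.iso_week for s in ordered)
    inc = [s.diapause_incidence_pct for s in ordered]
    year = ordered[0].iso_year
    for i, v in enumerate(inc):
        if v >= threshold_pct and all(
            u >= threshold_pct for u in inc[i + 1 : i + 1 + sustain]
        ):
            return CutoffResult(year, weeks[i], v, threshold_pct, weeks)
    return CutoffResult(year, None, None, threshold_pct, weeks)


def compute_cpp(
    cutoff: CutoffResult,
    site: Site,
    delay_weeks: int = 1,
    zenith_deg: float = DEFAULT_ZENITH_DEG,
    season_start_week: int | None = None,
) -> CppResult:
    """Maternal CPP: weekly photoperiod at ``cutoff_week - delay_weeks``.

    During the declining-photoperiod half of the season a larger maternal
    delay gives a longer (earlier) CPP.  ``season_start_week`` optionally
    guards against a delay that reaches back before the analysed season.
    """
    if not cutoff.found:
        raise ValueError("cannot compute a CPP without a detected cutoff week")
    if delay_weeks < 0:
        raise ValueError("delay_weeks must be >= 0")
    monday = dt.date.fromisocalendar(cutoff.iso_year, cutoff.cutoff_week, 1)
    maternal_monday = monday - dt.timedelta(weeks=delay_weeks)
    m_year, m_week = iso_week_of(maternal_monday)
    if season_start_week is not None and (
        m_year < cutoff.iso_year or m_week < season_start_week
    ):
        raise ValueError(
            f"maternal week {m_year}-W{m_week:02d} precedes season start "
            f"W{season_start_week:02d}"
        )
    pp = weekly_photoperiod(m_year, m_week, site, zenith_deg)
    return CppResult(
        iso_year=cutoff.iso_year,
        cutoff_week=cutoff.cutoff_week,
        delay_weeks=delay_weeks,
        maternal_iso_year=m_year,
        maternal_iso_week=m_week,
        cpp_min=pp.av_daylength_min,
    )


def average_cpp(results: Sequence[CppResult]) -> float:
    """Arithmetic mean CPP (minutes) across years, at one common delay."""
    if not results:
        raise ValueError("need at least one CppResult")
    delays = {r.delay_weeks for r in results}
    if len(delays) > 1:
        raise ValueError(f"mixed maternal delays: {sorted(delays)}")
    return sum(r.cpp_min for r in results) / len(results)


@dataclass(frozen=True)
class MortalitySummary:
    series: tuple[RateSummary, ...]
    mean_pct: float
    sd_pct: float
    single_week: bool = False


def mortality_series(
    records: Iterable[EggRecord],
    min_n: int = 1,
) -> MortalitySummary:
    """Weekly mortality with the season mean +/- SD (sample SD, ddof=1).

    With a single observed week the SD is reported as 0 and flagged.
    Unlike incidence, mortality is defined for cohorts without viable
    eggs, so only the ``min_n`` filter applies.
    """
    out: list[RateSummary] = []
    for c in tally_cohorts(records, group_by="week"):
        if c.total_tested < min_n or c.total_tested == 0:
            continue
        mort = 100.0 * (c.P + c.U) / c.total_tested
        out.append(
            RateSummary(
                iso_year=c.iso_year,
                iso_week=c.iso_week,
                n_tested=c.total_tested,
                n_viable=c.viable,
                hatching_success_pct=float("nan"),
                viability_pct=100.0 - mort,
                mortality_pct=mort,
                diapause_incidence_pct=float("nan"),
            )
        )
    if not out:
        raise ValueError("no cohorts to summarise")
    vals = [s.mortality_pct for s in out]
    mean = sum(vals) / len(vals)
    if len(vals) == 1:
        return MortalitySummary(tuple(out), mean, 0.0, single_week=True)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return MortalitySummary(tuple(out), mean, math.sqrt(var))
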