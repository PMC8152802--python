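"""Domain model for egg-cohort diapause surveillance data.

The unit of observation is a single egg censused from an ovitrap: where and
when it was collected, the outcome of the hatching/bleaching assay, and an
optional triplicate length/width measurement.  Eggs that were already
hatched, dried or damaged at collection carry the ``EXCLUDED`` status: they
stay visible in files for auditing but never enter a denominator.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Sequence

__all__ = [
    "EggStatus",
    "EggRecord",
    "CohortCounts",
    "MeteoDay",
    "MeteoWeek",
    "Site",
    "ValidationError",
    "tally_cohorts",
]


class ValidationError(ValueError):
    """An input violated a domain invariant."""


class EggStatus(str, Enum):
    """Outcome of the hatching assay followed by egg-shell bleaching.

    ``HATCHED`` and ``EMBRYONATED_UNHATCHED`` together are the viable eggs;
    an embryonated unhatched egg (full segmentation, pigmented ocelli and
    egg burster visible through the bleached shell) is the operational
    marker of diapause.  ``PARTIAL_EMBRYO`` and ``UNFERTILISED`` are dead
    eggs.  ``EXCLUDED`` marks eggs discarded before analysis.
    """

    HATCHED = "HATCHED"
    EMBRYONATED_UNHATCHED = "EMBRYONATED_UNHATCHED"
    PARTIAL_EMBRYO = "PARTIAL_EMBRYO"
    UNFERTILISED = "UNFERTILISED"
    EXCLUDED = "EXCLUDED"


VIABLE_STATUSES = frozenset({EggStatus.HATCHED, EggStatus.EMBRYONATED_UNHATCHED})


@dataclass(frozen=True)
class Site:
    """A collection or reference site given by geographic coordinates."""

    name: str
    latitude_deg: float
    longitude_deg: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValidationError(f"latitude out of range: {self.latitude_deg}")
        if not -180.0 <= self.longitude_deg <= 180.0:
            raise ValidationError(f"longitude out of range: {self.longitude_deg}")


#: The reference site used for photoperiod reproduction runs.
STRASBOURG = Site("Strasbourg", 48.58, 7.75)


@dataclass(frozen=True)
class EggRecord:
    """One egg's provenance, assay outcome and optional morphometry.

    ``length_reps_um``/``width_reps_um`` hold either zero or exactly three
    repeated measurements in micrometres (each measure is taken three times
    to dampen observation bias).  ``iso_year``/``iso_week`` are derived from
    ``collection_date`` under ISO 8601 week rules and validated against it.
    """

    egg_id: str
    site_id: str
    trap_id: str
    collection_date: dt.date
    status: EggStatus
    length_reps_um: tuple[float, ...] = ()
    width_reps_um: tuple[float, ...] = ()
    iso_year: int = field(default=0)
    iso_week: int = field(default=0)

    def __post_init__(self) -> None:
        y, w, _ = self.collection_date.isocalendar()
        if self.iso_year == 0 and self.iso_week == 0:
            object.__setattr__(self, "iso_year", y)
            object.__setattr__(self, "iso_week", w)
        elif (self.iso_year, self.iso_week) != (y, w):
            raise ValidationError(
                f"egg {self.egg_id}: iso_year/iso_week ({self.iso_year}, {self.iso_week}) "
                f"inconsistent with collection_date {self.collection_date} -> ({y}, {w})"
            )
        if not 1 <= self.iso_week <= 53:
            raise ValidationError(f"egg {self.egg_id}: iso_week {self.iso_week} out of range")
        nl, nw = len(self.length_reps_um), len(self.width_reps_um)
        if nl not in (0, 3) or nw not in (0, 3) or (nl == 0) != (nw == 0):
            raise ValidationError(
                f"egg {self.egg_id}: morphometry must have 0 or 3 reps per axis "
                f"(got {nl} length, {nw} width)"
            )
        if nl == 3:
            if any(v <= 0 for v in self.length_reps_um + self.width_reps_um):
                raise ValidationError(f"egg {self.egg_id}: non-positive measurement")
            ml = sum(self.length_reps_um) / 3.0
            mw = sum(self.width_reps_um) / 3.0
            if mw >= ml:
                raise ValidationError(
                    f"egg {self.egg_id}: mean width {mw:.1f} um not smaller than "
                    f"mean length {ml:.1f} um"
                )

    @property
    def has_morphometry(self) -> bool:
        return len(self.length_reps_um) == 3

    @property
    def is_viable(self) -> bool:
        return self.status in VIABLE_STATUSES

    @property
    def is_excluded(self) -> bool:
        return self.status is EggStatus.EXCLUDED


@dataclass(frozen=True)
class CohortCounts:
    """Status tallies for one (ISO year, week-or-bin) egg cohort.

    H: hatched, E: embryonated unhatched, P: partially embryonated,
    U: unfertilised.  EXCLUDED eggs are tracked separately and never
    contribute to any denominator.
    """

    iso_year: int
    iso_week: int
    H: int = 0
    E: int = 0
    P: int = 0
    U: int = 0
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.H, self.E, self.P, self.U, self.excluded) < 0:
            raise ValidationError("cohort counts must be non-negative")

    @property
    def total_tested(self) -> int:
        return self.H + self.E + self.P + self.U

    @property
    def viable(self) -> int:
        return self.H + self.E


@dataclass(frozen=True)
class MeteoDay:
    """One day of station weather: temperatures (degC), sunshine (min), rain (mm)."""

    date: dt.date
    tmin_C: float
    tmax_C: float
    sunshine_min: float
    rainfall_mm: float

    def __post_init__(self) -> None:
        if self.tmin_C > self.tmax_C:
            raise ValidationError(f"{self.date}: tmin {self.tmin_C} > tmax {self.tmax_C}")
        if self.sunshine_min < 0:
            raise ValidationError(f"{self.date}: negative sunshine")
        if self.rainfall_mm < 0:
            raise ValidationError(f"{self.date}: negative rainfall")


@dataclass(frozen=True)
class MeteoWeek:
    """Weekly aggregates of the daily station record.

    The eight temperature summaries follow surveillance convention:
    weekly mean/min/max of the daily minimum and of the daily maximum.
    ``partial`` flags weeks with fewer than 7 days of coverage; such weeks
    are aggregated over the available days rather than dropped.
    """

    iso_year: int
    iso_week: int
    avTmin: float
    avTmax: float
    minTmin: float
    minTmax: float
    maxTmin: float
    maxTmax: float
    avSun: float
    cumulSun: float
    avRain: float
    cumulRain: float
    avPhotoperiod_min: float | None = None
    n_days: int = 7

    @property
    def partial(self) -> bool:
        return self.n_days < 7


def tally_cohorts(
    records: Iterable[EggRecord],
    group_by: Literal["week", "two_week_bin"] = "week",
) -> list[CohortCounts]:
    """Tally egg statuses per ISO week (or per two-week bin) and year.

    EXCLUDED eggs are counted in the ``excluded`` slot only.  Two-week bins
    start at the first observed collection week of each season and pair
    consecutive ISO weeks; a bin is labelled by its first week.  Empty
    groups are absent from the output, which is sorted by (year, week).
    """
    per_year_weeks: dict[int, set[int]] = defaultdict(set)
    rows: list[EggRecord] = list(records)
    for r in rows:
        per_year_weeks[r.iso_year].add(r.iso_week)

    def bin_of(year: int, week: int) -> int:
        if group_by == "week":
            return week
        start = min(per_year_weeks[year])
        return start + 2 * ((week - start) // 2)

    if group_by not in ("week", "two_week_bin"):
        raise ValueError(f"unknown grouping {group_by!r}")

    counts: dict[tuple[int, int], dict[str, int]] = defaultdict(
        lambda: {"H": 0, "E": 0, "P": 0, "U": 0, "excluded": 0}
    )
    slot = {
        EggStatus.HATCHED: "H",
        EggStatus.EMBRYONATED_UNHATCHED: "E",
        EggStatus.PARTIAL_EMBRYO: "P",
        EggStatus.UNFERTILISED: "U",
        EggStatus.EXCLUDED: "excluded",
    }
    for r in rows:
        key = (r.iso_year, bin_of(r.iso_year, r.iso_week))
        counts[key][slot[r.status]] += 1
    return [
        CohortCounts(iso_year=y, iso_week=w, **c)
        for (y, w), c in sorted(counts.items())
    ]
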