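"""Astronomical day length and weekly photoperiod.

Day length is the sunrise-to-sunset duration from the classical sunrise
equation,

    cos(omega0) = (cos z - sin(phi) sin(delta)) / (cos(phi) cos(delta)),
    duration    = 2 * omega0 / 15 deg * 60 min,

with solar declination ``delta`` evaluated once per day (at noon) from the
low-accuracy solar-position series of Meeus, which is accurate to well
under 0.01 deg — far below the minute-level rounding of published
sunrise/sunset tables.  The horizon convention is set by the zenith angle
``z``:

``90.0``
    geometric: centre of the solar disc on the true horizon;
``90.567`` (default)
    apparent centre: 34 arcmin of atmospheric refraction at the horizon;
``90.833``
    apparent upper limb: refraction plus 16 arcmin of solar semidiameter,
    the convention of civil sunrise/sunset tables.

The 90.567 deg default is the convention that reproduces the published
weekly day lengths for Strasbourg used in the critical-photoperiod
computation (all within about 2 min); the other two are available via the
``zenith_deg`` argument.  Weekly photoperiod is the arithmetic mean of the
seven Monday-to-Sunday daily durations of an ISO week.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

from .core import Site, ValidationError

__all__ = [
    "ZENITH_GEOMETRIC",
    "ZENITH_REFRACTION",
    "ZENITH_UPPER_LIMB",
    "DEFAULT_ZENITH_DEG",
    "PhotoperiodWeek",
    "solar_declination",
    "day_length_min",
    "weekly_photoperiod",
    "iso_week_of",
    "minutes_to_hhmm",
]

ZENITH_GEOMETRIC = 90.0
ZENITH_REFRACTION = 90.567
ZENITH_UPPER_LIMB = 90.833
DEFAULT_ZENITH_DEG = ZENITH_REFRACTION


@dataclass(frozen=True)
class PhotoperiodWeek:
    """Weekly mean astronomical day length at a site, in minutes."""

    iso_year: int
    iso_week: int
    av_daylength_min: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.av_daylength_min <= 1440.0:
            raise ValidationError("day length outside [0, 1440] minutes")

    @property
    def hhmm(self) -> str:
        return minutes_to_hhmm(self.av_daylength_min)


def solar_declination(date: dt.date) -> float:
    """Solar declination (radians) at noon UT, via the Meeus series."""
    jd = date.toordinal() + 1721425.0  # JD at 12:00 UT
    T = (jd - 2451545.0) / 36525.0
    L0 = math.radians((280.46646 + 36000.76983 * T + 0.0003032 * T * T) % 360.0)
    M = math.radians(357.52911 + 35999.05029 * T - 0.0001537 * T * T)
    C = math.radians(
        (1.914602 - 0.004817 * T - 0.000014 * T * T) * math.sin(M)
        + (0.019993 - 0.000101 * T) * math.sin(2 * M)
        + 0.000289 * math.sin(3 * M)
    )
    omega = math.radians(125.04 - 1934.136 * T)
    # apparent longitude: aberration and nutation correction
    lam = L0 + C + math.radians(-0.00569 - 0.00478 * math.sin(omega))
    eps = math.radians(23.439291 - 0.0130042 * T + 0.00256 * math.cos(omega))
    return math.asin(math.sin(eps) * math.sin(lam))


def day_length_min(
    date: dt.date, site: Site, zenith_deg: float = DEFAULT_ZENITH_DEG
) -> float:
    """Sunrise-to-sunset duration in minutes for one calendar day.

    Polar day/night clip to 1440/0.  Longitude does not enter: only the
    duration, not the clock times, is computed.
    """
    if not 0.0 < zenith_deg < 180.0:
        raise ValueError(f"zenith_deg must be in (0, 180), got {zenith_deg}")
    delta = solar_declination(date)
    phi = math.radians(site.latitude_deg)
    z = math.radians(zenith_deg)
    denom = math.cos(phi) * math.cos(delta)
    if denom == 0.0:  # pole: sun circles at constant altitude
        up = math.pi / 2 - abs(phi - delta) >= math.pi / 2 - z
        return 1440.0 if up else 0.0
    cos_omega = (math.cos(z) - math.sin(phi) * math.sin(delta)) / denom
    if cos_omega <= -1.0:
        return 1440.0  # polar day
    if cos_omega >= 1.0:
        return 0.0  # polar night
    omega_deg = math.degrees(math.acos(cos_omega))
    return 2.0 * omega_deg / 15.0 * 60.0


def iso_week_of(date: dt.date) -> tuple[int, int]:
    """(ISO week-year, ISO week) of a date.

    Weeks start on Monday; week 1 is the week containing the year's first
    Thursday, so the week-year can differ from the calendar year around
    1 January.
    """
    y, w, _ = date.isocalendar()
    return y, w


def weekly_photoperiod(
    iso_year: int,
    iso_week: int,
    site: Site,
    zenith_deg: float = DEFAULT_ZENITH_DEG,
) -> PhotoperiodWeek:
    """Mean day length over the 7 Monday-Sunday days of an ISO week."""
    try:
        monday = dt.date.fromisocalendar(iso_year, iso_week, 1)
    except ValueError as exc:
        raise ValueError(f"invalid ISO week {iso_year}-W{iso_week:02d}: {exc}") from exc
    total = sum(
        day_length_min(monday + dt.timedelta(days=i), site, zenith_deg)
        for i in range(7)
    )
    return PhotoperiodWeek(iso_year, iso_week, total / 7.0)


def minutes_to_hhmm(minutes: float) -> str:
    """Format a duration as e.g. ``'13 h 07 min'`` (rounded to the minute)."""
    m = int(round(minutes))
    return f"{m // 60} h {m % 60:02d} min"
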