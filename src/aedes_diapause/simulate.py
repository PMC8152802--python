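"""Seeded generator of synthetic ovitrap seasons.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every stage can be exercised and checked against known
generative truth without any field data:

* **Abundance** — weekly egg intensity is bimodal (a large summer peak
  around week 28 and a smaller autumn peak around week 40); per trap-week
  counts are Poisson with the weekly intensity split evenly over traps.
* **Diapause** — each non-dead egg is in diapause with probability

      p(w) = p0 + (1 - p0) * expit(k * (w - w* + 1/2) + c),
      c = logit((1/2 - p0) / (1 - p0)),

  a constitutive floor ``p0`` (a fraction of eggs is laid in diapause all
  season) plus a photoperiodically driven logistic in week number ``w``.
  The offset places the 50% point of the curve at the boundary ``w* - 1/2``,
  so the crossing happens *within* week ``w*``: ``w*`` is the first integer
  week with p >= 1/2 (p(w*) > 1/2, p(w* - 1) < 1/2), and in the
  infinitely-steep limit every egg before ``w*`` is non-diapausing and
  every egg from ``w*`` on is diapausing.  Diapausing eggs are recorded as
  embryonated unhatched, the rest as hatched.
* **Mortality** — each egg is dead with probability ``m`` before the
  diapause draw, split between partially embryonated and unfertilised.
* **Morphometry** — a fraction of eggs carries triplicate measurements;
  true width follows the late-season line ``intercept + slope * w`` plus a
  constant offset for the early regime (weeks up to ``early_end_week``),
  with Gaussian egg-level and replicate-level noise; length is Gaussian
  and uncorrelated with week.
* **Weather** — smooth seasonal sinusoids plus noise; only the ordering
  invariants (tmin <= tmax, non-negative sunshine/rain) are promised, not
  climatological realism.

Identical seeds give byte-identical outputs.  The truth ledger records
every generative parameter and the per-week intensities/probabilities, so
pipeline estimates can be compared with :func:`truth_vs_estimate`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import EggRecord, EggStatus, MeteoDay

__all__ = [
    "SimConfig",
    "simulate_season",
    "diapause_probability",
    "simulate_incidence_counts",
    "truth_vs_estimate",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a synthetic two-year ovitrap season.

    Defaults emulate the field conditions the pipeline targets: a
    two-year season over weeks 20-45 with 12 traps, bimodal abundance, a
    10% constitutive diapause floor rising to ~100% by mid-October with
    the 50% crossing in week 36, egg width drifting up by ~0.75 um/week
    late in the season, and ~17% egg mortality.
    """

    seed: int = 1
    years: tuple[int, ...] = (2019, 2020)
    week_start: int = 20
    week_end: int = 45
    n_traps: int = 12

    # weekly abundance intensity (eggs across all traps)
    peak1_week: float = 28.0
    peak1_height: float = 1500.0
    peak1_sd: float = 4.0
    peak2_week: float = 40.0
    peak2_height: float = 600.0
    peak2_sd: float = 2.0
    base_intensity: float = 10.0

    # diapause curve
    p0: float = 0.10
    crossing_week: float = 36.0
    steepness: float = 0.9

    # morphometry
    width_slope: float = 0.7474
    width_intercept: float = 151.24
    width_sd: float = 6.0
    length_mean: float = 616.0
    length_sd: float = 30.0
    early_offset_um: float = 8.0
    early_end_week: int = 24
    rep_sd: float = 2.0
    morph_fraction: float = 0.10

    # mortality
    mortality: float = 0.17
    partial_fraction: float = 0.5  # share of dead eggs that are PARTIAL_EMBRYO

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 < 0.5:
            raise ValueError("p0 must be in [0, 0.5) so the 50% point is reachable")
        if not 0.0 <= self.mortality < 1.0:
            raise ValueError("mortality must be in [0, 1)")
        if self.peak1_height < 0 or self.peak2_height < 0 or self.base_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if not 0.0 < self.morph_fraction <= 1.0:
            raise ValueError("morph_fraction must be in (0, 1]")

    @property
    def run_id(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def diapause_probability(
    week: float | np.ndarray,
    p0: float = 0.10,
    crossing_week: float = 36.0,
    steepness: float = 0.9,
) -> np.ndarray:
    """Generative diapause probability p(week): floor plus logistic rise.

    The 50% point of the curve sits at ``crossing_week - 1/2``, making
    ``crossing_week`` the first integer week at or above 50%.
    """
    c = logit((0.5 - p0) / (1.0 - p0))
    z = steepness * (np.asarray(week, dtype=float) - crossing_week + 0.5) + c
    return p0 + (1.0 - p0) * expit(z)


def _weekly_intensity(cfg: SimConfig, weeks: np.ndarray) -> np.ndarray:
    lam = (
        cfg.base_intensity
        + cfg.peak1_height * np.exp(-0.5 * ((weeks - cfg.peak1_week) / cfg.peak1_sd) ** 2)
        + cfg.peak2_height * np.exp(-0.5 * ((weeks - cfg.peak2_week) / cfg.peak2_sd) ** 2)
    )
    return lam


def _simulate_meteo(cfg: SimConfig, rng: np.random.Generator) -> list[MeteoDay]:
    out: list[MeteoDay] = []
    for year in cfg.years:
        start = dt.date.fromisocalendar(year, max(cfg.week_start - 2, 1), 1)
        end = dt.date.fromisocalendar(year, min(cfg.week_end + 1, 52), 7)
        n = (end - start).days + 1
        dates = [start + dt.timedelta(days=i) for i in range(n)]
        doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
        seasonal = 10.0 + 9.0 * np.sin(2 * np.pi * (doy - 105.0) / 365.0)
        tmin = seasonal + rng.normal(0.0, 2.0, n)
        spread = 8.0 + rng.gamma(2.0, 1.0, n)
        tmax = tmin + spread
        sunshine = np.clip(
            300.0 + 240.0 * np.sin(2 * np.pi * (doy - 80.0) / 365.0)
            + rng.normal(0.0, 90.0, n),
            0.0,
            None,
        )
        wet = rng.random(n) < 0.35
        rain = np.where(wet, rng.gamma(1.2, 4.0, n), 0.0)
        for d, a, b, s, r in zip(dates, tmin, tmax, sunshine, rain):
            out.append(MeteoDay(d, float(a), float(b), float(s), float(r)))
    return out


def simulate_season(
    cfg: SimConfig,
) -> tuple[list[EggRecord], list[MeteoDay], dict[str, Any]]:
    """Generate one synthetic multi-year season.

    Returns (egg records, daily weather, truth ledger).  The truth ledger
    holds the full config, the per-week intensity and diapause
    probability, and realized per-week tallies of the latent states.
    """
    rng = np.random.default_rng(cfg.seed)
    weeks = np.arange(cfg.week_start, cfg.week_end + 1)
    lam = _weekly_intensity(cfg, weeks.astype(float))
    p_week = diapause_probability(
        weeks.astype(float), cfg.p0, cfg.crossing_week, cfg.steepness
    )

    records: list[EggRecord] = []
    realized: list[dict[str, Any]] = []
    for year in cfg.years:
        for wi, week in enumerate(weeks):
            sunday = dt.date.fromisocalendar(year, int(week), 7)
            n_by_trap = rng.poisson(lam[wi] / cfg.n_traps, size=cfg.n_traps)
            n_week = int(n_by_trap.sum())
            if n_week == 0:
                continue
            dead = rng.random(n_week) < cfg.mortality
            partial = rng.random(n_week) < cfg.partial_fraction
            diap = rng.random(n_week) < p_week[wi]
            measured = rng.random(n_week) < cfg.morph_fraction
            width_mu = cfg.width_intercept + cfg.width_slope * float(week)
            if week <= cfg.early_end_week:
                width_mu += cfg.early_offset_um
            true_w = rng.normal(width_mu, cfg.width_sd, n_week)
            true_l = rng.normal(cfg.length_mean, cfg.length_sd, n_week)
            # keep the spheroid geometry sane: width strictly below length
            true_w = np.clip(true_w, 120.0, None)
            true_l = np.maximum(true_l, true_w + 50.0)
            reps_w = true_w[:, None] + rng.normal(0.0, cfg.rep_sd, (n_week, 3))
            reps_l = true_l[:, None] + rng.normal(0.0, cfg.rep_sd, (n_week, 3))

            trap_of = np.repeat(np.arange(cfg.n_traps), n_by_trap)
            for j in range(n_week):
                if dead[j]:
                    status = (
                        EggStatus.PARTIAL_EMBRYO if partial[j] else EggStatus.UNFERTILISED
                    )
                elif diap[j]:
                    status = EggStatus.EMBRYONATED_UNHATCHED
                else:
                    status = EggStatus.HATCHED
                has_m = bool(measured[j])
                records.append(
                    EggRecord(
                        egg_id=f"Y{year}W{week:02d}T{trap_of[j]:02d}E{j:05d}",
                        site_id="synthetic",
                        trap_id=f"T{trap_of[j]:02d}",
                        collection_date=sunday,
                        status=status,
                        length_reps_um=tuple(np.round(reps_l[j], 2)) if has_m else (),
                        width_reps_um=tuple(np.round(reps_w[j], 2)) if has_m else (),
                    )
                )
            realized.append(
                {
                    "iso_year": year,
                    "iso_week": int(week),
                    "n_eggs": n_week,
                    "n_dead": int(dead.sum()),
                    "n_viable": int(n_week - dead.sum()),
                    "n_diapause_viable": int((~dead & diap).sum()),
                    "n_with_morphometry": int(measured.sum()),
                }
            )

    meteo = _simulate_meteo(cfg, rng)
    truth: dict[str, Any] = {
        "run_id": cfg.run_id,
        "config": dataclasses.asdict(cfg),
        "weeks": weeks.tolist(),
        "intensity": lam.tolist(),
        "p_week": p_week.tolist(),
        "realized": realized,
    }
    return records, meteo, truth


def simulate_incidence_counts(
    rng: np.random.Generator,
    weeks: Sequence[int] = range(26, 44),
    n_per_week: int = 200,
    p0: float = 0.10,
    crossing_week: float = 36.0,
    steepness: float = 0.9,
) -> pd.DataFrame:
    """Weekly binomial diapause counts from the generative curve.

    A lightweight season: ``n_per_week`` viable eggs per week, each in
    diapause with probability p(week).  Columns: iso_week, n, n_diapause.
    """
    wk = np.asarray(list(weeks), dtype=int)
    p = diapause_probability(wk.astype(float), p0, crossing_week, steepness)
    k = rng.binomial(n_per_week, p)
    return pd.DataFrame({"iso_week": wk, "n": n_per_week, "n_diapause": k})


def truth_vs_estimate(
    truth: Mapping[str, Any], estimates: Mapping[str, Any]
) -> pd.DataFrame:
    """Tabulate generative parameters against pipeline estimates.

    ``estimates`` maps parameter names (a subset of p0, crossing_week,
    width_slope, mortality, plus any ``beta_*``) to estimated values and
    must carry the ``run_id`` of the dataset it was computed from; a
    mismatched run id is an error, since comparing across runs is
    meaningless.  Optional per-parameter tolerances (``tol``) yield a
    verdict column.
    """
    if "run_id" not in estimates:
        raise ValueError("estimates must carry the run_id of their input dataset")
    if estimates["run_id"] != truth["run_id"]:
        raise ValueError(
            f"run_id mismatch: truth {truth['run_id']} vs estimates {estimates['run_id']}"
        )
    cfg = truth["config"]
    tol = estimates.get("tol", {})
    rows = []
    for name, est in estimates.items():
        if name in ("run_id", "tol"):
            continue
        true_val = cfg.get(name)
        err = None if true_val is None or est is None else float(est) - float(true_val)
        row = {
            "parameter": name,
            "truth": true_val,
            "estimate": est,
            "error": err,
        }
        if name in tol and err is not None:
            row["within_tol"] = bool(abs(err) <= tol[name])
        rows.append(row)
    return pd.DataFrame(rows)
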