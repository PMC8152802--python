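"""Single entry point chaining every analysis stage into a season report.

The report layer orchestrates only: every number it emits is produced by
one of the stage functions (rates, photoperiod, morphometrics, GLM,
seasonality) and copied into the report, never recomputed here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import pandas as pd

from . import __version__
from .core import EggRecord, MeteoDay, Site
from .glm import build_design, select_by_aic
from .morphometrics import (
    assign_groups,
    morphometry_frame,
    seasonal_regression,
    split_season,
    weekly_medians,
    wilcoxon_one_tailed,
)
from .rates import (
    DEFAULT_MIN_N,
    average_cpp,
    compute_cpp,
    detect_cutoff,
    mortality_series,
    weekly_incidence,
)
from .seasonality import abundance_series, activity_threshold, weekly_meteo

__all__ = ["ReportConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReportConfig:
    min_n: int = DEFAULT_MIN_N
    delays: tuple[int, ...] = (0, 1, 2)
    default_delay: int = 1
    diapause_window: tuple[int, int] = (26, 44)
    early_range: tuple[int, int] = (20, 24)
    late_range: tuple[int, int] = (26, 43)
    bin_width: int = 2
    threshold_pct: float = 50.0
    sustain: int = 2


def _rate_dict(s: Any) -> dict[str, Any]:
    return dataclasses.asdict(s)


def run_all(
    records: Sequence[EggRecord],
    meteo_days: Sequence[MeteoDay],
    site: Site,
    config: ReportConfig = ReportConfig(),
) -> dict[str, Any]:
    """Run the full season analysis and return a JSON-serialisable report.

    Per year: abundance series, weekly rate series, mortality summary,
    sustained 50% cutoff, CPP at each configured maternal delay,
    morphometric regressions (late-season width and volume on week),
    ND/M/D group contrast on width; across years: the mean CPP at the
    default delay, the AIC-selected logistic diapause model, and the
    egg-laying temperature threshold.  Deterministic given inputs.
    """
    records = list(records)
    if not records:
        raise ValueError("no egg records")
    report: dict[str, Any] = {
        "package_version": __version__,
        "site": dataclasses.asdict(site),
        "config": dataclasses.asdict(config),
        "years": {},
    }
    meteo_weeks = weekly_meteo(meteo_days)
    morph = morphometry_frame(r for r in records if not r.is_excluded)

    cpps_default_delay = []
    years = sorted({r.iso_year for r in records})
    for year in years:
        yr_records = [r for r in records if r.iso_year == year]
        yr: dict[str, Any] = {}

        ab = abundance_series(yr_records, bin_width=config.bin_width, site=site.name)
        yr["abundance"] = {
            "bin_width": ab.bin_width,
            "bins": [dataclasses.asdict(b) for b in ab.bins],
            "season_total": ab.season_total.get(year),
            "mean_per_bin": ab.mean_per_bin.get(year),
            "sd_per_bin": ab.sd_per_bin.get(year),
        }

        series = weekly_incidence(
            yr_records, min_n=config.min_n, week_range=config.diapause_window
        )
        yr["rates"] = [_rate_dict(s) for s in series]

        mort = mortality_series(yr_records, min_n=config.min_n)
        yr["mortality"] = {
            "mean_pct": mort.mean_pct,
            "sd_pct": mort.sd_pct,
            "n_weeks": len(mort.series),
        }

        if series:
            cutoff = detect_cutoff(series, config.threshold_pct, config.sustain)
        else:
            cutoff = None
        if cutoff is not None and cutoff.found:
            yr["cutoff"] = dataclasses.asdict(cutoff)
            yr["cpp"] = {}
            for delay in config.delays:
                cpp = compute_cpp(cutoff, site, delay_weeks=delay)
                yr["cpp"][str(delay)] = {
                    "cpp_min": cpp.cpp_min,
                    "cpp_hhmm": cpp.cpp_hhmm,
                    "maternal_week": cpp.maternal_iso_week,
                }
                if delay == config.default_delay:
                    cpps_default_delay.append(cpp)
        else:
            yr["cutoff"] = {"cutoff_week": None, "note": "no sustained crossing"}
            yr["cpp"] = {}

        ym = morph[morph["iso_year"] == year]
        yr["morphometrics"] = {}
        if len(ym) >= 3:
            for resp in ("width_um", "volume_e3mm3"):
                med = weekly_medians(ym, resp)
                _, late = split_season(med, config.early_range, config.late_range)
                if len(late) >= 3:
                    fit = seasonal_regression(late, response_name=resp)
                    yr["morphometrics"][resp] = dataclasses.asdict(fit)
            if cutoff is not None and cutoff.found:
                groups = assign_groups(
                    cutoff.cutoff_week, sorted(ym["iso_week"].unique())
                )
                nd_weeks = set(groups.weeks("ND")) & set(
                    range(config.diapause_window[0], config.diapause_window[1] + 1)
                )
                d_weeks = set(groups.weeks("D"))
                nd = ym[ym["iso_week"].isin(nd_weeks)]["width_um"]
                d = ym[ym["iso_week"].isin(d_weeks)]["width_um"]
                if len(nd) > 0 and len(d) > 0:
                    w = wilcoxon_one_tailed(d, nd, alternative="greater")
                    yr["group_contrast_width"] = dataclasses.asdict(w)
                    yr["groups"] = {
                        "ND": sorted(nd_weeks),
                        "M": groups.weeks("M"),
                        "D": groups.weeks("D"),
                    }
        report["years"][str(year)] = yr

    if cpps_default_delay:
        report["average_cpp"] = {
            "delay_weeks": config.default_delay,
            "cpp_min": average_cpp(cpps_default_delay),
            "n_years": len(cpps_default_delay),
        }

    egg_weeks = {(r.iso_year, r.iso_week) for r in records}
    try:
        report["activity_threshold_C"] = activity_threshold(egg_weeks, meteo_weeks)
    except ValueError as exc:
        report["activity_threshold_C"] = None
        logger.warning("activity threshold unavailable: %s", exc)

    try:
        design = build_design(r for r in records if not r.is_excluded)
        candidates = (
            ("x1", "x2", "year", "x1:x2") if len(years) > 1 else ("x1", "x2", "x1:x2")
        )
        best, table = select_by_aic(design, candidates)
        report["glm"] = {
            "best_formula": " + ".join(best.terms) or "1",
            "coefficients": dict(zip(best.column_names, best.coefficients)),
            "standard_errors": dict(zip(best.column_names, best.standard_errors)),
            "aic": best.aic,
            "log_likelihood": best.log_likelihood,
            "n": best.n,
            "converged": best.converged,
            "separation": best.separation,
            "ranking": table.to_dict("records"),
        }
    except ValueError as exc:
        report["glm"] = None
        logger.warning("GLM stage skipped: %s", exc)

    return report


def report_text(report: dict[str, Any]) -> str:
    """Human-readable one-page summary of a season report."""
    lines = [f"Season report (aedes-diapause {report['package_version']})"]
    for year, yr in report["years"].items():
        lines.append(f"\n== {year} ==")
        ab = yr["abundance"]
        lines.append(
            f"  eggs: {ab['season_total']} total, "
            f"{ab['mean_per_bin']:.0f} +/- {ab['sd_per_bin']:.0f} per {ab['bin_width']}-week bin"
        )
        mort = yr["mortality"]
        lines.append(
            f"  mortality: {mort['mean_pct']:.2f} +/- {mort['sd_pct']:.2f} % "
            f"over {mort['n_weeks']} weeks"
        )
        cw = yr["cutoff"].get("cutoff_week")
        if cw is None:
            lines.append("  50% diapause cutoff: not reached")
        else:
            lines.append(f"  50% diapause cutoff: week {cw}")
            for delay, cpp in sorted(yr["cpp"].items()):
                lines.append(
                    f"    CPP (maternal delay {delay} wk): {cpp['cpp_hhmm']}"
                )
        for resp, fit in yr.get("morphometrics", {}).items():
            lines.append(
                f"  {resp} ~ week: slope {fit['slope']:.4f} "
                f"(adj R2 {fit['r_squared_adj']:.2f}, p {fit['p_value']:.2g})"
            )
    if "average_cpp" in report:
        ac = report["average_cpp"]
        m = ac["cpp_min"]
        lines.append(
            f"\naverage CPP over {ac['n_years']} year(s), delay {ac['delay_weeks']} wk: "
            f"{int(m // 60)} h {int(round(m % 60)):02d} min"
        )
    if report.get("activity_threshold_C") is not None:
        lines.append(f"egg-laying temperature threshold: {report['activity_threshold_C']:.1f} C")
    if report.get("glm"):
        lines.append(f"AIC-selected diapause model: {report['glm']['best_formula']}")
    return "\n".join(lines) + "\n"
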