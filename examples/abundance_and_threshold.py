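"""Egg-abundance seasonality, the temperature activity threshold and
covariate associations.

Uses the built-in published biweekly totals for the Reichstett site and a
simulated weather record for the weekly aggregation steps.
"""

from aedes_diapause import (
    SimConfig,
    abundance_series,
    activity_threshold,
    simulate_season,
    spearman,
    weekly_incidence,
    weekly_meteo,
)
from aedes_diapause.datasets import reichstett_biweekly_counts

counts = reichstett_biweekly_counts()
ab = abundance_series(counts, bin_width=2, site="Reichstett")
for year in (2019, 2020):
    print(f"{year}: {ab.season_total[year]:,} eggs, "
          f"{ab.mean_per_bin[year]:.0f} +/- {ab.sd_per_bin[year]:.0f} per two weeks")

records, meteo_days, _ = simulate_season(SimConfig(seed=5, years=(2019,)))
weeks = weekly_meteo(meteo_days)
egg_weeks = {(r.iso_year, r.iso_week) for r in records}
thr = activity_threshold(egg_weeks, weeks)
print(f"\nsimulated season: egg laying observed above ~{thr:.1f} C "
      "(mean of the two seasonal temperature minima over egg weeks)")

series = weekly_incidence(records, min_n=6, week_range=(26, 44))
rho = spearman(
    [s.iso_week for s in series],
    [s.diapause_incidence_pct for s in series],
    var_x="week", var_y="diapause incidence",
)
print(f"\nSpearman({rho.var_x}, {rho.var_y}): rho={rho.rho:.2f}, "
      f"p={rho.p_value:.1e}, n={rho.n}")
print("-> incidence rises with calendar week as photoperiod shortens.")
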