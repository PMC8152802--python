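"""Egg morphometry over the season: volume, trend and group contrasts.

Late-season (diapause-destined) eggs are wider and larger.  Weekly median
width is regressed on week, and eggs after the cutoff window (group D)
are compared with pre-cutoff eggs (group ND) by a one-tailed rank test.
"""

from aedes_diapause import SimConfig, egg_volume, simulate_season
from aedes_diapause.morphometrics import (
    assign_groups,
    morphometry_frame,
    seasonal_regression,
    weekly_medians,
    wilcoxon_one_tailed,
)

print("spheroid volume (pi/6 * L * W^2):")
for L, W in [(616, 177), (625, 179)]:
    print(f"  L={L} um, W={W} um -> {egg_volume(L, W):.1f} x 10^-3 mm^3")

records, _, truth = simulate_season(SimConfig(seed=3, years=(2019,), morph_fraction=0.2))
frame = morphometry_frame(records)
fit = seasonal_regression(weekly_medians(frame, "width_um"), week_range=(26, 43))
print(f"\nweekly median width ~ week (26-43): slope {fit.slope:.3f} um/week "
      f"(adj R2 {fit.r_squared_adj:.2f}, p {fit.p_value:.1e})")
print(f"  generative slope was {truth['config']['width_slope']}")

groups = assign_groups(36, sorted(frame["iso_week"].unique()))
nd = frame[frame["iso_week"].isin([w for w in groups.weeks("ND") if w >= 26])]
d = frame[frame["iso_week"].isin(groups.weeks("D"))]
test = wilcoxon_one_tailed(d["width_um"], nd["width_um"], alternative="greater")
print(f"\ngroup D (weeks {min(groups.weeks('D'))}-{max(groups.weeks('D'))}) vs "
      f"ND: {test.effect_pct:.2f}% wider, W={test.statistic:.0f}, "
      f"p={test.p_value:.2e}")
print("-> late-season eggs are measurably wider, but widths overlap, so "
      "morphology alone cannot classify a single egg.")
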