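"""From egg-status tallies to diapause incidence and the 50% cutoff week.

Hatched (H) and embryonated-unhatched (E) eggs are the viable ones;
diapause incidence = 100 * E / (H + E).  The cutoff detector returns the
first week at or above 50% whose next two observed weeks stay there.
"""

from aedes_diapause import detect_cutoff, rates_from_counts
from aedes_diapause.core import CohortCounts

weekly_counts = {
    33: (52, 8, 7, 5),    # week: (H, E, P, U)
    34: (41, 17, 6, 4),
    35: (30, 26, 5, 6),
    36: (22, 30, 8, 3),   # first week with E/(H+E) >= 50%
    37: (14, 38, 5, 5),
    38: (6, 49, 7, 4),
}

series = []
print("week  n    diapause%  viability%")
for week, (h, e, p, u) in weekly_counts.items():
    r = rates_from_counts(CohortCounts(2019, week, H=h, E=e, P=p, U=u))
    series.append(r)
    print(f"{week}   {r.n_tested:4d}   {r.diapause_incidence_pct:6.1f}   "
          f"{r.viability_pct:8.1f}")

cutoff = detect_cutoff(series)
print(f"\nSustained 50% crossing: week {cutoff.cutoff_week} "
      f"({cutoff.incidence_at_cutoff_pct:.1f}% incidence)")
print("-> eggs laid from this week on are predominantly in diapause.")
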