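"""Day length and the maternal critical photoperiod (CPP) at Strasbourg.

The 50% diapause-incidence cutoff was reached in ISO week 36 of 2019 and
week 37 of 2020.  The CPP is the day length the ovipositing females
experienced, i.e. the weekly photoperiod one maternal delay earlier.
"""

from aedes_diapause import STRASBOURG, average_cpp, compute_cpp, weekly_photoperiod
from aedes_diapause.rates import CutoffResult

for year, week in [(2019, 36), (2020, 37)]:
    pp = weekly_photoperiod(year, week, STRASBOURG)
    print(f"{year} cutoff week {week}: mean day length {pp.hhmm}")

print("\nCPP by maternal delay (weeks between photoperiod perception and collection):")
cpps_delay1 = []
for year, week in [(2019, 36), (2020, 37)]:
    cutoff = CutoffResult(year, week, 55.0, 50.0, ())
    for delay in (0, 1, 2):
        cpp = compute_cpp(cutoff, STRASBOURG, delay_weeks=delay)
        print(f"  {year}, delay {delay}: {cpp.cpp_hhmm} "
              f"(maternal week {cpp.maternal_iso_week})")
        if delay == 1:
            cpps_delay1.append(cpp)

avg = average_cpp(cpps_delay1)
print(f"\nAverage CPP across years at delay 1: {int(avg // 60)} h "
      f"{round(avg % 60):02d} min")
print("-> the day length below which half of all eggs laid are in diapause.")
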