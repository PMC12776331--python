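"""Score a 6-h sleep-deprivation day against a baseline day.

Builds a scripted SD day (enforced wake ZT0-6, dense recovery NREM ZT6-11)
and a normal baseline, then prints the hourly NREM time course, the
cumulative recovery-sleep NREM, and dark-phase REM for both days.
"""

from sleeparch import Hypnogram, rebound_analysis

baseline = Hypnogram.from_states(("W" * 2 + "N" * 3 + "R" * 1) * 1440)
sd_day = Hypnogram.from_states(
    "W" * 2160                     # ZT0-6: enforced wakefulness
    + ("N" * 5 + "W") * 300        # ZT6-11: NREM-dense recovery sleep
    + ("W" * 3 + "N" * 2 + "R") * 470  # ZT11-18.8: mixed
    + "W" * (8640 - 2160 - 1800 - 2820))

res = rebound_analysis(baseline, sd_day)

print("ZT hour | baseline NREM (min) | SD-day NREM (min)")
for zt in range(12):
    print(f"  {zt:2d}    |       {res.hourly_nrem_min['baseline'][zt]:5.1f}"
          f"         |      {res.hourly_nrem_min['sd'][zt]:5.1f}")

print(f"\nCumulative NREM over the ZT6-11 recovery window: "
      f"baseline {res.cumulative_rs_nrem_min['baseline']:.0f} min, "
      f"SD day {res.cumulative_rs_nrem_min['sd']:.0f} min")
print(f"Dark-phase REM: baseline {res.dark_rem_min['baseline']:.0f} min, "
      f"SD day {res.dark_rem_min['sd']:.0f} min")
print("\nThe SD day shows zero sleep during deprivation and an NREM rebound "
      "in the recovery window, the signature of intact sleep homeostasis.")
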