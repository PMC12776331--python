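"""Factorial group statistics on a simulated genotype × sex cohort.

Simulates wildtype and knock-in groups (the knock-in preset doubles
dark-phase wake bout length), runs the two-way Genotype × Sex ANOVA on each
animal's mean dark-phase wake bout duration, follows up with Fisher's LSD,
and demonstrates the per-frequency-bin REM spectrum comparison with
Holm-Šídák correction.
"""

import numpy as np

from sleeparch.recovery import (bout_ratio_experiment,
                                theta_detection_replicate)

res = bout_ratio_experiment(seed=11, n_per_group=8, n_days=2.0)
print(f"KI/WT dark-phase wake bout duration ratio: {res.ratio:.2f} "
      "(generator truth: 2.0)")
print(f"Genotype main effect: F = {res.genotype_f:.1f}, p = {res.genotype_p:.2e}")

cells = {}
for row in res.per_animal:
    cells.setdefault(f"{row['genotype']}:{row['sex']}", []).append(
        row["dark_wake_bout_s"])
means = {k: float(np.mean(v)) for k, v in cells.items()}
print("\nCell means (s):", {k: round(v, 1) for k, v in means.items()})

hit, ranges = theta_detection_replicate(seed=11)
print(f"\nPer-bin REM spectrum comparison flags theta-range deficit: {hit}")
print("Significant frequency ranges (Hz):",
      [(round(lo, 2), round(hi, 2)) for lo, hi in ranges[:5]], "...")
print("\nThe injected effects (wake-bout doubling, REM theta ×0.7) are "
      "recovered by the same statistics applied to real cohorts.")
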