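"""End-to-end parameter-recovery experiments on simulated cohorts.

These run the full pipeline — generator, architecture metrics, spectra,
group statistics — against the generator's known truth and are the basis of
the package's self-validation: a 2×2 genotype × sex cohort with the mutant
preset's dark-phase wake-bout doubling must be recovered as a duration
ratio near 2 with a detectable genotype main effect, and the preset's REM
theta-power reduction (×0.7) must be flagged by the per-bin spectral
comparison in nearly every replicate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .hypnogram import Phase, StateLabel, detect_bouts, bout_stats
from .simulate import SimParams, mutant_params, simulate_cohort
from .spectral import SpectralParams, state_spectrum
from .stats import per_bin_compare, twoway_anova

__all__ = ["BoutRatioResult", "bout_ratio_experiment",
           "theta_detection_replicate", "theta_detection_experiment"]


def _design(n_per_group: int):
    return [{"group": f"{g}_{s}", "genotype": g, "sex": s, "n": n_per_group}
            for g in ("WT", "KI") for s in ("M", "F")]


def _params_by_group(base: SimParams):
    return {"WT_M": base, "WT_F": base,
            "KI_M": mutant_params(base, sex="M"),
            "KI_F": mutant_params(base, sex="F")}


@dataclass(frozen=True)
class BoutRatioResult:
    ratio: float                # KI / WT group-mean dark wake bout duration
    genotype_p: float
    genotype_f: float
    per_animal: list[dict]


def bout_ratio_experiment(seed: int = 0, n_per_group: int = 8,
                          n_days: float = 2.0,
                          base: SimParams | None = None) -> BoutRatioResult:
    """Recover the dark-phase wake-bout duration ratio from a 2×2 cohort.

    Simulates hypnograms only (no signals), computes each animal's mean
    dark-phase wake bout duration, and tests the genotype main effect with
    the two-way genotype × sex ANOVA.  The mutant preset doubles the
    dark-phase wake bout length, so the true ratio is 2.
    """
    base = base or SimParams()
    cohort = simulate_cohort(_design(n_per_group), _params_by_group(base),
                             seed=seed, n_days=n_days)
    rows = []
    for a in cohort:
        bouts = detect_bouts(a.hypnogram)
        bs = bout_stats(bouts, a.hypnogram, "DARK")
        rows.append({"animal_id": a.animal_id, "genotype": a.genotype,
                     "sex": a.sex,
                     "dark_wake_bout_s": bs[StateLabel.WAKE]["mean_bout_duration_s"]})
    vals = np.array([r["dark_wake_bout_s"] for r in rows], dtype=float)
    geno = [r["genotype"] for r in rows]
    sex = [r["sex"] for r in rows]
    ratio = vals[np.array(geno) == "KI"].mean() / vals[np.array(geno) == "WT"].mean()
    tab = twoway_anova(vals, geno, sex, names=("Genotype", "Sex"))
    return BoutRatioResult(float(ratio), float(tab["Genotype"]["p"]),
                           float(tab["Genotype"]["F"]), rows)


def theta_detection_replicate(seed: int, n_per_group: int = 8,
                              n_days: float = 1 / 24,
                              eeg_fs: float = 128.0, nfft: int = 2048
                              ) -> tuple[bool, tuple[tuple[float, float], ...]]:
    """One replicate of the REM theta-power detection experiment.

    Simulates a cohort with EEG at a reduced sampling rate, computes each
    animal's transition-excluded REM spectrum, and runs the per-bin
    comparison between genotypes (both sexes pooled).  Returns whether any
    rejected bin lies in the theta band (6-9 Hz), plus the significant
    ranges found.
    """
    base = dataclasses.replace(SimParams(), eeg_fs=eeg_fs)
    sparams = SpectralParams(fs=eeg_fs, nfft=nfft, f_min=0.5, f_max=60.0)
    cohort = simulate_cohort(_design(n_per_group), _params_by_group(base),
                             seed=seed, n_days=n_days, with_eeg=True)
    spectra = {"WT": [], "KI": []}
    mask = sparams.analysis_mask()
    freqs = sparams.frequencies()[mask]
    for a in cohort:
        spec = state_spectrum(a.eeg, a.hypnogram, StateLabel.REM, sparams)
        if spec.missing:  # very short recording without a >2-epoch REM bout
            continue
        spectra[a.genotype].append(spec.power[mask])
    res = per_bin_compare(np.vstack(spectra["WT"]), np.vstack(spectra["KI"]),
                          freqs)
    hit = any(lo < 9.0 and hi >= 6.0 for lo, hi in res.significant_ranges_hz)
    return hit, res.significant_ranges_hz


def theta_detection_experiment(seed: int = 0, n_replicates: int = 100,
                               **kw) -> float:
    """Fraction of replicates in which the injected REM theta deficit is
    detected by the per-bin comparison."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_replicates).astype(np.int64) % (2 ** 31)
    hits = sum(theta_detection_replicate(int(s), **kw)[0] for s in child_seeds)
    return hits / n_replicates
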