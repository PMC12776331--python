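"""Synthetic cohorts with known ground truth for pipeline validation.

The generator emulates the statistical structure of rodent telemetry
recordings that the analysis assumes, with every parameter it injects known
exactly, so estimator accuracy can be asserted against truth:

* **Hypnograms** follow a diurnally modulated semi-Markov (alternating
  renewal) process: at each state exit the next state is drawn from
  state-specific exit probabilities (wake never transitions directly into
  REM, mirroring the rescoring rules), and the bout length (>= 2 epochs) is
  drawn from a geometric or discretized-lognormal distribution whose mean
  depends on state and light/dark phase (the phase of the bout's onset).
  Generated hypnograms are by construction fixpoints of the rescoring rules.
* **EEG** is synthesized per epoch as a sum of independent band-limited
  Gaussian noise components with state-specific band weights (NREM
  delta-dominant, REM theta-peaked, Wake broadband); the expected power per
  band is analytically known.  Signal continuity across epoch boundaries is
  not enforced — the analysis is strictly per-epoch, so the discontinuity is
  invisible to it.
* **Activity** counts are Poisson per minute with a state × phase rate;
  **subcutaneous temperature** follows a cosine circadian rhythm plus state
  offsets and AR(1) noise.

The ``mutant`` preset mirrors the qualitative phenotype of amyloid-
precursor-protein knock-in mice — dark-phase wake bouts twice as long,
fewer REM entries (×0.6), reduced REM theta power (×0.7), with an extra REM
deficit in females.  These are presets for validation, not estimates of any
real cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .hypnogram import Hypnogram, Phase, StateLabel
from .spectral import DEFAULT_BANDS, BandDefinition

__all__ = ["SimParams", "SimulatedAnimal", "mutant_params",
           "simulate_hypnogram", "simulate_eeg", "simulate_activity",
           "simulate_tsc", "simulate_cohort", "expected_state_fractions"]

_STATES = (StateLabel.WAKE, StateLabel.NREM, StateLabel.REM)


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults emulate an adult wildtype mouse.

    Mean bout lengths are in epochs (10-s epochs: light-phase wake ~2 min,
    NREM ~3 min, REM ~90 s; dark-phase wake ~5 min).  Exit probabilities
    define the embedded state chain with W→R fixed at 0.  EEG band weights
    are amplitude weights on band-limited unit-variance noise, so expected
    band power scales with weight².
    """

    epoch_s: float = 10.0
    # mean bout length in epochs, per state x phase
    mean_bout_epochs: dict[tuple[StateLabel, Phase], float] = field(
        default_factory=lambda: {
            (StateLabel.WAKE, Phase.LIGHT): 12.0,
            (StateLabel.WAKE, Phase.DARK): 30.0,
            (StateLabel.NREM, Phase.LIGHT): 18.0,
            (StateLabel.NREM, Phase.DARK): 12.0,
            (StateLabel.REM, Phase.LIGHT): 9.0,
            (StateLabel.REM, Phase.DARK): 8.0,
        })
    bout_distribution: str = "geometric"  # or "lognormal"
    lognormal_sigma: float = 0.6
    # exit-transition probabilities per phase; W->R is structurally 0
    exit_probs: dict[Phase, dict[tuple[StateLabel, StateLabel], float]] = field(
        default_factory=lambda: {
            Phase.LIGHT: {(StateLabel.WAKE, StateLabel.NREM): 1.0,
                          (StateLabel.NREM, StateLabel.WAKE): 0.70,
                          (StateLabel.NREM, StateLabel.REM): 0.30,
                          (StateLabel.REM, StateLabel.WAKE): 0.90,
                          (StateLabel.REM, StateLabel.NREM): 0.10},
            Phase.DARK: {(StateLabel.WAKE, StateLabel.NREM): 1.0,
                         (StateLabel.NREM, StateLabel.WAKE): 0.85,
                         (StateLabel.NREM, StateLabel.REM): 0.15,
                         (StateLabel.REM, StateLabel.WAKE): 0.90,
                         (StateLabel.REM, StateLabel.NREM): 0.10},
        })
    # EEG synthesis: per-state amplitude weight per band
    eeg_fs: float = 500.0
    eeg_band_weights: dict[StateLabel, dict[str, float]] = field(
        default_factory=lambda: {
            StateLabel.WAKE: {"delta": 1.0, "theta": 1.2, "alpha": 0.8,
                              "beta": 0.7, "low_gamma": 0.6},
            StateLabel.NREM: {"delta": 3.0, "theta": 1.0, "alpha": 0.5,
                              "beta": 0.3, "low_gamma": 0.2},
            StateLabel.REM: {"delta": 1.0, "theta": 2.5, "alpha": 0.6,
                             "beta": 0.3, "low_gamma": 0.3},
        })
    eeg_amplitude: float = 1.0
    bands: dict[str, BandDefinition] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    # activity: Poisson counts per minute, per state x phase
    activity_rate: dict[tuple[StateLabel, Phase], float] = field(
        default_factory=lambda: {
            (StateLabel.WAKE, Phase.LIGHT): 4.0,
            (StateLabel.WAKE, Phase.DARK): 10.0,
            (StateLabel.NREM, Phase.LIGHT): 0.2,
            (StateLabel.NREM, Phase.DARK): 0.3,
            (StateLabel.REM, Phase.LIGHT): 0.1,
            (StateLabel.REM, Phase.DARK): 0.1,
        })
    # subcutaneous temperature
    tsc_mesor_c: float = 36.3
    tsc_amplitude_c: float = 0.7
    tsc_acrophase_zt_h: float = 18.0
    tsc_state_offset_c: dict[StateLabel, float] = field(
        default_factory=lambda: {StateLabel.WAKE: 0.25, StateLabel.NREM: -0.10,
                                 StateLabel.REM: 0.0})
    tsc_ar1_phi: float = 0.8
    tsc_noise_sd_c: float = 0.10

    def __post_init__(self):
        for key, m in self.mean_bout_epochs.items():
            if m < 2:
                raise ValueError(f"mean bout length for {key} must be >= 2 epochs "
                                 f"(got {m})")
        for phase, probs in self.exit_probs.items():
            for (src, dst), p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"exit probability {src}->{dst} out of [0,1]")
                if src == StateLabel.WAKE and dst == StateLabel.REM and p != 0:
                    raise ValueError("direct wake-to-REM transitions are disallowed")
            for src in _STATES:
                tot = sum(p for (s, _), p in probs.items() if s == src)
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(f"exit probabilities from {src.name} in "
                                     f"{phase.name} sum to {tot}, not 1")
        if any(r < 0 for r in self.activity_rate.values()):
            raise ValueError("activity rates must be nonnegative")


def mutant_params(base: SimParams | None = None, sex: str = "M",
                  dark_wake_bout_mult: float = 2.0,
                  rem_entry_mult: float = 0.6,
                  female_rem_entry_mult: float = 0.85,
                  rem_theta_mult: float = 0.7) -> SimParams:
    """Knock-in preset: longer dark wake bouts, fewer REM entries, weaker
    REM theta; females carry an additional REM-entry deficit."""
    p = base or SimParams()
    mean = dict(p.mean_bout_epochs)
    mean[(StateLabel.WAKE, Phase.DARK)] *= dark_wake_bout_mult
    exit_probs = {}
    m = rem_entry_mult * (female_rem_entry_mult if sex == "F" else 1.0)
    for phase, probs in p.exit_probs.items():
        q = dict(probs)
        nr = q[(StateLabel.NREM, StateLabel.REM)] * m
        q[(StateLabel.NREM, StateLabel.REM)] = nr
        q[(StateLabel.NREM, StateLabel.WAKE)] = 1.0 - nr
        exit_probs[phase] = q
    weights = {s: dict(w) for s, w in p.eeg_band_weights.items()}
    weights[StateLabel.REM]["theta"] *= rem_theta_mult
    return replace(p, mean_bout_epochs=mean, exit_probs=exit_probs,
                   eeg_band_weights=weights)


@dataclass(frozen=True)
class SimulatedAnimal:
    """One synthetic animal: traces plus the exact parameters that made them."""

    animal_id: str
    genotype: str
    sex: str
    hypnogram: Hypnogram
    eeg: np.ndarray | None
    activity: np.ndarray | None
    tsc: np.ndarray | None
    params: SimParams
    seed: int


# ---------------------------------------------------------------------------
# hypnogram simulation
# ---------------------------------------------------------------------------

def _draw_bout_length(rng: np.random.Generator, mean: float, params: SimParams) -> int:
    if params.bout_distribution == "geometric":
        # support {2, 3, ...}: 2 + Geometric0(p) with mean 2 + (1-p)/p = mean
        p = 1.0 / (mean - 1.0)
        return 2 + int(rng.geometric(p)) - 1  # numpy geometric has support {1,..}
    if params.bout_distribution == "lognormal":
        sigma = params.lognormal_sigma
        mu = np.log(mean) - 0.5 * sigma ** 2
        return max(2, int(round(rng.lognormal(mu, sigma))))
    raise ValueError(f"unknown bout distribution {params.bout_distribution!r}")


def simulate_hypnogram(params: SimParams, n_days: float = 1.0,
                       seed: int | np.random.SeedSequence = 0,
                       zt_start_s: float = 0.0) -> Hypnogram:
    """Simulate a semi-Markov hypnogram of ``n_days`` × 24 h.

    States alternate by the embedded exit chain; each bout's length is drawn
    from the state × phase distribution, the phase being that of the bout's
    onset ZT.  The output is reproducible given the seed and is a fixpoint
    of the rescoring rules (no wake-to-REM transition, no singleton REM —
    every bout has >= 2 epochs).
    """
    rng = np.random.default_rng(seed)
    n_epochs = int(round(n_days * 86400 / params.epoch_s))
    labels = np.empty(n_epochs, dtype=np.int8)
    epochs_per_day = int(round(86400 / params.epoch_s))
    light_lo, light_hi = 0.0, 12.0

    state = StateLabel.WAKE
    pos = 0
    while pos < n_epochs:
        zt_h = ((zt_start_s / params.epoch_s + pos) % epochs_per_day) \
            * params.epoch_s / 3600.0
        phase = Phase.LIGHT if light_lo <= zt_h < light_hi else Phase.DARK
        length = _draw_bout_length(rng, params.mean_bout_epochs[(state, phase)],
                                   params)
        end = min(pos + length, n_epochs)
        labels[pos:end] = state.value
        pos = end
        probs = params.exit_probs[phase]
        dests = [d for d in _STATES if d != state]
        weights = np.array([probs.get((state, d), 0.0) for d in dests])
        state = dests[int(rng.choice(len(dests), p=weights / weights.sum()))]
    # the final (truncated) run may be a singleton REM; rescore it to keep
    # the constructed-compliance guarantee
    if labels[-1] == StateLabel.REM.value and (n_epochs < 2 or
                                               labels[-2] != StateLabel.REM.value):
        labels[-1] = labels[-2] if n_epochs >= 2 else StateLabel.WAKE.value
    return Hypnogram(labels, params.epoch_s, zt_start_s)


def expected_state_fractions(params: SimParams, phase: Phase) -> dict[StateLabel, float]:
    """Stationary time-in-state fractions of the semi-Markov chain in one phase.

    With embedded-chain stationary distribution π and mean bout lengths L,
    the long-run fraction of time in state i is π_i·L_i / Σ_j π_j·L_j
    (renewal-reward theorem).  Exact for a chain held in a single phase;
    within a phase of a diurnal simulation it holds up to boundary effects.
    """
    probs = params.exit_probs[phase]
    P = np.zeros((3, 3))
    for (src, dst), p in probs.items():
        P[src.value, dst.value] = p
    evals, evecs = np.linalg.eig(P.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    pi = pi / pi.sum()
    L = np.array([params.mean_bout_epochs[(s, phase)] for s in _STATES])
    w = pi * L
    w = w / w.sum()
    return {s: float(w[s.value]) for s in _STATES}


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def _band_noise_epoch(rng: np.random.Generator, n: int, fs: float,
                      band: BandDefinition, weight: float) -> np.ndarray:
    """Band-limited Gaussian noise with RMS amplitude = weight.

    Synthesized in the frequency domain: i.i.d. complex Gaussian rfft
    coefficients inside [lo, hi), zero elsewhere, scaled so the expected
    time-domain variance equals weight².
    """
    freqs = np.arange(n // 2 + 1) * fs / n
    mask = band.mask(freqs)
    k = int(mask.sum())
    if k == 0 or weight == 0:
        return np.zeros(n)
    # interior rfft bins X_k = σ(g + ig') give Var(x_t) = 4kσ²/n²;
    # σ = w·n/(2√k) yields per-sample variance exactly weight²
    sigma = weight * n / (2.0 * np.sqrt(k))
    spec = np.zeros(n // 2 + 1, dtype=complex)
    spec[mask] = sigma * (rng.normal(size=k) + 1j * rng.normal(size=k))
    return np.fft.irfft(spec, n=n)


def simulate_eeg(h: Hypnogram, params: SimParams,
                 seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Synthesize a single-channel EEG matched to the hypnogram, epoch by epoch.

    Each epoch is an independent sum of band-limited Gaussian components
    with the epoch state's band weights; expected variance contributed by a
    band equals (amplitude × weight)².  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(h.epoch_s * params.eeg_fs))
    out = np.empty(h.n_epochs * n)
    band_list = list(params.bands.values())
    for i, code in enumerate(h.labels):
        weights = params.eeg_band_weights[StateLabel(code)]
        epoch = np.zeros(n)
        for band in band_list:
            w = weights.get(band.name, 0.0)
            if w:
                epoch += _band_noise_epoch(rng, n, params.eeg_fs, band,
                                           params.eeg_amplitude * w)
        out[i * n:(i + 1) * n] = epoch
    return out


def simulate_activity(h: Hypnogram, params: SimParams,
                      seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Per-minute Poisson activity counts with state × phase rates.

    The minute's state is the state of its first epoch (10-s epochs: 6 per
    minute)."""
    rng = np.random.default_rng(seed)
    per_min = max(1, int(round(60.0 / h.epoch_s)))
    n_min = h.n_epochs // per_min
    phases = h.phase_of_epochs()
    rates = np.array([params.activity_rate[(StateLabel(h.labels[i * per_min]),
                                            Phase(phases[i * per_min]))]
                      for i in range(n_min)])
    return rng.poisson(rates).astype(int)


def simulate_tsc(h: Hypnogram, params: SimParams,
                 seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Per-minute subcutaneous temperature: cosine rhythm + state offset + AR(1)."""
    rng = np.random.default_rng(seed)
    per_min = max(1, int(round(60.0 / h.epoch_s)))
    n_min = h.n_epochs // per_min
    zt_h = (h.zt_start_s / 3600.0 + np.arange(n_min) / 60.0) % 24.0
    base = params.tsc_mesor_c + params.tsc_amplitude_c * np.cos(
        2 * np.pi * (zt_h - params.tsc_acrophase_zt_h) / 24.0)
    offsets = np.array([params.tsc_state_offset_c[StateLabel(h.labels[i * per_min])]
                        for i in range(n_min)])
    noise = np.empty(n_min)
    eps = rng.normal(scale=params.tsc_noise_sd_c, size=n_min)
    prev = 0.0
    for i in range(n_min):
        prev = params.tsc_ar1_phi * prev + eps[i]
        noise[i] = prev
    return base + offsets + noise


def simulate_cohort(design: list[dict], params_by_group: dict[str, SimParams],
                    seed: int | np.random.SeedSequence = 0, n_days: float = 1.0,
                    with_eeg: bool = False, with_activity: bool = False,
                    with_tsc: bool = False) -> list[SimulatedAnimal]:
    """Simulate a factorial cohort with per-animal seeds spawned from ``seed``.

    ``design`` is a list of group dicts ``{"group": key, "genotype": ...,
    "sex": ..., "n": int}``; ``params_by_group`` maps the group key to its
    SimParams (exact ground truth, stored on every animal).
    """
    master = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    total = sum(g["n"] for g in design)
    children = master.spawn(total)
    animals = []
    idx = 0
    for grp in design:
        params = params_by_group[grp["group"]]
        for j in range(grp["n"]):
            ss = children[idx]
            sub = ss.spawn(4)
            h = simulate_hypnogram(params, n_days=n_days, seed=sub[0])
            eeg = simulate_eeg(h, params, seed=sub[1]) if with_eeg else None
            act = simulate_activity(h, params, seed=sub[2]) if with_activity else None
            tsc = simulate_tsc(h, params, seed=sub[3]) if with_tsc else None
            animals.append(SimulatedAnimal(
                animal_id=f"{grp['group']}_{j:02d}", genotype=grp["genotype"],
                sex=grp["sex"], hypnogram=h, eeg=eeg, activity=act, tsc=tsc,
                params=params, seed=idx))
            idx += 1
    return animals
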