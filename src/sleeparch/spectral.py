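"""Per-epoch EEG power spectra, state-conditioned averages and band powers.

Each 10-s scoring epoch is Fourier-transformed on a fine frequency grid
(fs/nfft per bin; 500 Hz / 8192 points ≈ 0.061 Hz at the defaults, so the
printed band boundaries 4.88, 6.35 and 7.08 Hz land on bin centres).  Power
is scaled so that the summed spectrum equals the time-domain energy of the
windowed epoch (Parseval), which makes band powers additive over disjoint
bands.

State-conditioned spectra average per-epoch spectra over all epochs of a
state except the first two epochs of every bout (transition epochs, excluded
because state-boundary epochs carry mixed physiology); bouts of two or fewer
epochs therefore contribute nothing.

Standard frequency bands (half-open [lo, hi) so touching edges never
double-count a bin): delta 0.5-4, theta 6-9, alpha 9-12, beta 12-30 and low
gamma 30-60 Hz.  The 4-6 Hz gap is deliberately unassigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import get_window

from .hypnogram import Hypnogram, StateLabel, detect_bouts

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralParams",
    "BandDefinition",
    "DEFAULT_BANDS",
    "EpochSpectrum",
    "StateSpectrum",
    "epoch_psd",
    "epoch_samples",
    "included_epoch_indices",
    "state_spectrum",
    "band_power",
    "band_ratio",
    "nrem_delta_timecourse",
    "normalize_to_baseline",
]


@dataclass(frozen=True)
class SpectralParams:
    """FFT analysis parameters.

    fs : sampling rate in samples/s (default 500)
    nfft : FFT length; epochs shorter than nfft are zero-padded (default 8192,
        giving fs/nfft ≈ 0.0610 Hz bins for 10-s epochs at 500 Hz)
    window_fn : "hann" (default) or "rectangular"
    f_min, f_max : analysis range in Hz (defaults 0.5 and 60)
    """

    fs: float = 500.0
    nfft: int = 8192
    window_fn: str = "hann"
    f_min: float = 0.5
    f_max: float = 60.0

    def __post_init__(self):
        if self.fs <= 0 or self.nfft < 2:
            raise ValueError("fs must be positive and nfft >= 2")
        if self.window_fn not in ("hann", "rectangular"):
            raise ValueError("window_fn must be 'hann' or 'rectangular'")
        if not 0 <= self.f_min < self.f_max <= self.fs / 2:
            raise ValueError("need 0 <= f_min < f_max <= fs/2")

    @property
    def bin_hz(self) -> float:
        return self.fs / self.nfft

    def frequencies(self) -> np.ndarray:
        """One-sided frequency grid k·fs/nfft, k = 0..nfft//2."""
        return np.arange(self.nfft // 2 + 1) * self.bin_hz

    def analysis_mask(self) -> np.ndarray:
        f = self.frequencies()
        return (f >= self.f_min) & (f <= self.f_max)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band; membership is half-open [lo_hz, hi_hz)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band requires lo_hz < hi_hz")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo_hz) & (freqs < self.hi_hz)


DEFAULT_BANDS: dict[str, BandDefinition] = {
    b.name: b for b in (
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 6.0, 9.0),
        BandDefinition("alpha", 9.0, 12.0),
        BandDefinition("beta", 12.0, 30.0),
        BandDefinition("low_gamma", 30.0, 60.0),
    )
}


@dataclass(frozen=True)
class EpochSpectrum:
    """One-sided power spectrum of a single epoch (energy-scaled)."""

    power: np.ndarray
    bin_hz: float

    @property
    def n_bins(self) -> int:
        return int(self.power.size)

    def frequencies(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hz


@dataclass(frozen=True)
class StateSpectrum:
    """Mean per-bin power over included epochs of one state.

    ``power`` is None when no epochs survive the transition exclusion.
    """

    state: StateLabel
    power: np.ndarray | None
    bin_hz: float
    n_epochs_included: int
    exclusion_rule: int = 2

    @property
    def missing(self) -> bool:
        return self.power is None

    def frequencies(self) -> np.ndarray:
        if self.power is None:
            raise ValueError("spectrum is missing (no included epochs)")
        return np.arange(self.power.size) * self.bin_hz


def epoch_psd(samples: np.ndarray, params: SpectralParams) -> EpochSpectrum:
    """Energy-scaled one-sided power spectrum of one epoch.

    The epoch is windowed, zero-padded to ``nfft`` and transformed; bins are
    scaled so that ``sum(power)`` equals the time-domain energy of the
    windowed signal (Parseval).  Deterministic for fixed input.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be 1-D")
    if not np.isfinite(x).all():
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite sample at index {bad} within the epoch")
    if x.size > params.nfft:
        raise ValueError(f"epoch has {x.size} samples > nfft={params.nfft}")
    if params.window_fn == "hann":
        w = get_window("hann", x.size, fftbins=True)
    else:
        w = np.ones(x.size)
    xw = x * w
    X = np.fft.rfft(xw, n=params.nfft)
    p = (np.abs(X) ** 2) / params.nfft
    # one-sided: double the interior bins so the sum equals full-spectrum energy
    p[1:-1] *= 2.0
    if params.nfft % 2 == 1:
        p[-1] *= 2.0
    return EpochSpectrum(p, params.bin_hz)


def epoch_samples(recording: np.ndarray, epoch_index: int, h: Hypnogram,
                  params: SpectralParams) -> np.ndarray:
    """Slice the raw samples of one scoring epoch out of the recording."""
    n = int(round(h.epoch_s * params.fs))
    start = epoch_index * n
    if start + n > recording.size:
        raise ValueError(f"epoch {epoch_index} extends past the recording")
    return np.asarray(recording, dtype=float)[start:start + n]


def included_epoch_indices(h: Hypnogram, state: StateLabel,
                           exclusion: int = 2) -> np.ndarray:
    """Epoch indices of ``state`` entering spectral averages.

    Per bout of the state, the first ``exclusion`` epochs are dropped; runs
    shorter than a bout (singletons) never appear.  The number of indices is
    Σ max(0, bout_len - exclusion) over the state's bouts.
    """
    idx: list[int] = []
    for b in detect_bouts(h):
        if b.state == state and b.n_epochs > exclusion:
            idx.extend(range(b.onset_epoch + exclusion, b.onset_epoch + b.n_epochs))
    return np.asarray(idx, dtype=int)


def state_spectrum(recording: np.ndarray, h: Hypnogram, state: StateLabel,
                   params: SpectralParams, exclusion: int = 2) -> StateSpectrum:
    """Mean spectrum over all included epochs of one state.

    Transition epochs (the first ``exclusion`` epochs of every bout) are
    excluded; if nothing remains the result is missing and a warning is
    logged (typical for REM in short windows).
    """
    idx = included_epoch_indices(h, state, exclusion)
    if idx.size == 0:
        logger.warning("no %s epochs remain after excluding the first %d "
                       "epochs of each bout; spectrum is missing",
                       state.name, exclusion)
        return StateSpectrum(state, None, params.bin_hz, 0, exclusion)
    acc = None
    for i in idx:
        p = epoch_psd(epoch_samples(recording, int(i), h, params), params).power
        acc = p if acc is None else acc + p
    return StateSpectrum(state, acc / idx.size, params.bin_hz, int(idx.size), exclusion)


def band_power(spec: StateSpectrum | EpochSpectrum, band: BandDefinition) -> float:
    """Total power in ``band`` (sum of bins with lo <= f < hi)."""
    power = spec.power
    if power is None:
        raise ValueError("cannot take band power of a missing spectrum")
    return float(power[band.mask(spec.frequencies())].sum())


def band_ratio(spec: StateSpectrum | EpochSpectrum, num_band: BandDefinition,
               den_band: BandDefinition) -> float | None:
    """Ratio of two band powers; None (missing) when the denominator is 0."""
    den = band_power(spec, den_band)
    if den == 0:
        return None
    return band_power(spec, num_band) / den


def nrem_delta_timecourse(recording: np.ndarray, h: Hypnogram,
                          params: SpectralParams,
                          hours: Sequence[int] | None = None,
                          band: BandDefinition = DEFAULT_BANDS["delta"],
                          state: StateLabel = StateLabel.NREM,
                          exclusion: int = 2) -> dict[int, float | None]:
    """Hourly slow-wave activity: mean NREM delta power per ZT hour.

    For each requested ZT hour, the mean delta-band power over included NREM
    epochs whose onset falls in that hour; hours without included NREM
    epochs map to None (missing, never 0).
    """
    if hours is None:
        hours = sorted(set(np.floor(h.zt_hours()).astype(int) % 24))
    idx = included_epoch_indices(h, state, exclusion)
    hour_of = np.floor(h.zt_hours()).astype(int) % 24
    out: dict[int, float | None] = {}
    for zt in hours:
        sel = idx[hour_of[idx] == zt] if idx.size else idx
        if sel.size == 0:
            out[int(zt)] = None
            continue
        vals = [band_power(epoch_psd(epoch_samples(recording, int(i), h, params),
                                     params), band) for i in sel]
        out[int(zt)] = float(np.mean(vals))
    return out


def normalize_to_baseline(series: dict[int, float | None],
                          baseline_value: float) -> dict[int, float | None]:
    """Express each hour as a percentage of a baseline power (100 = baseline).

    Scale-invariant: multiplying the recording's amplitude by c scales both
    numerator and baseline power by c², leaving the normalized series fixed.
    """
    if not baseline_value > 0:
        raise ValueError("baseline_value must be positive")
    return {k: (None if v is None else 100.0 * v / baseline_value)
            for k, v in series.items()}
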