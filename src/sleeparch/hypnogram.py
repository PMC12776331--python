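"""Hypnograms, rescoring rules, bout detection and sleep-architecture summaries.

A hypnogram is a sequence of arousal-state labels (Wake, NREM, REM), one per
fixed-length scoring epoch (10 s by default), aligned to zeitgeber time (ZT;
ZT0 = lights on).  Everything downstream — bout analytics, state-conditioned
spectra, perturbation protocols — operates on this object.

Two rescoring rules clean up automated staging before analysis:

1. a single isolated REM epoch is rescored as the state of the previous
   epoch (a REM bout requires at least two consecutive epochs), and
2. REM directly following Wake is rescored as Wake (sleep-onset REM periods
   are excluded; in healthy rodents REM is entered from NREM).

A *bout* of a state is a maximal run of >= 2 consecutive epochs of that
state; single-epoch runs count toward time-in-state but never toward bout
counts or durations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StateLabel",
    "Phase",
    "Hypnogram",
    "Bout",
    "ArchitectureSummary",
    "BoutHistogram",
    "apply_scoring_rules",
    "detect_bouts",
    "epoch_window_mask",
    "time_in_state",
    "state_fractions_exact",
    "hourly_profile",
    "bout_stats",
    "wake_bout_histogram",
    "summarize_architecture",
    "DEFAULT_HISTOGRAM_EDGES_S",
]

#: Wake-bout duration histogram boundaries in seconds (open-ended first and
#: last bins: <60 s and >260 s).
DEFAULT_HISTOGRAM_EDGES_S: tuple[float, ...] = (60.0, 100.0, 140.0, 180.0, 220.0, 260.0)


class StateLabel(IntEnum):
    """Arousal state of one scoring epoch."""

    WAKE = 0
    NREM = 1
    REM = 2

    @classmethod
    def from_token(cls, token: str) -> "StateLabel":
        """Parse a one-letter state token (``W``/``N``/``R``), case-insensitive."""
        try:
            return _TOKEN_MAP[token.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown state token {token!r}; expected one of W, N, R")

    @property
    def token(self) -> str:
        return "WNR"[self.value]


_TOKEN_MAP = {"W": StateLabel.WAKE, "N": StateLabel.NREM, "R": StateLabel.REM,
              "WAKE": StateLabel.WAKE, "NREM": StateLabel.NREM, "REM": StateLabel.REM}


class Phase(IntEnum):
    """Light/dark phase of the LD cycle."""

    LIGHT = 0
    DARK = 1


@dataclass(frozen=True)
class Hypnogram:
    """A scored recording: one state label per epoch on a ZT-aligned grid.

    Parameters
    ----------
    labels:
        State per epoch, stored as an int8 array of :class:`StateLabel` values.
    epoch_s:
        Seconds per scoring epoch (default 10).
    zt_start_s:
        Zeitgeber time of the first epoch in seconds; 0 = lights on.
    lights_on_h, lights_off_h:
        Phase boundaries in ZT hours; defaults define an LD 12:12 cycle.
    """

    labels: np.ndarray
    epoch_s: float = 10.0
    zt_start_s: float = 0.0
    lights_on_h: float = 0.0
    lights_off_h: float = 12.0

    def __post_init__(self):
        arr = np.asarray(self.labels, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if not np.isin(arr, [s.value for s in StateLabel]).all():
            bad = sorted(set(arr.tolist()) - {s.value for s in StateLabel})
            raise ValueError(f"invalid state codes in labels: {bad}")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if not 0 <= self.zt_start_s < 86400:
            raise ValueError("zt_start_s must lie in [0, 86400)")
        object.__setattr__(self, "labels", arr)

    @classmethod
    def from_states(cls, states: Iterable[StateLabel | int | str], **kw) -> "Hypnogram":
        """Build from any iterable of StateLabel, int codes or ``W/N/R`` tokens."""
        vals = [StateLabel.from_token(s) if isinstance(s, str) else StateLabel(s)
                for s in states]
        return cls(np.array([int(v) for v in vals], dtype=np.int8), **kw)

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def zt_seconds(self) -> np.ndarray:
        """ZT of each epoch's onset in seconds, wrapped to [0, 86400)."""
        return (self.zt_start_s + np.arange(self.n_epochs) * self.epoch_s) % 86400.0

    def zt_hours(self) -> np.ndarray:
        return self.zt_seconds() / 3600.0

    def phase_of_epochs(self) -> np.ndarray:
        """Light/dark phase of each epoch (by its onset ZT)."""
        zt_h = self.zt_hours()
        light = _in_cyclic_interval(zt_h, self.lights_on_h, self.lights_off_h)
        return np.where(light, Phase.LIGHT.value, Phase.DARK.value).astype(np.int8)

    def states(self) -> list[StateLabel]:
        return [StateLabel(v) for v in self.labels]


@dataclass(frozen=True)
class Bout:
    """A maximal run of >= 2 consecutive epochs of one state."""

    state: StateLabel
    onset_epoch: int
    n_epochs: int
    epoch_s: float = 10.0
    phase: Phase = Phase.LIGHT

    def __post_init__(self):
        if self.n_epochs < 2:
            raise ValueError("a bout requires at least 2 epochs")

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s


@dataclass(frozen=True)
class ArchitectureSummary:
    """Per-state time and bout metrics inside one analysis window.

    ``time_pct``/``time_min`` are derived floats; the exact quantities are the
    integer epoch counts (``n_epochs``) and exact seconds (``time_s``).
    ``mean_bout_duration_s`` is None (missing, never 0) where a state has no
    bouts in the window.
    """

    window: str
    n_epochs: dict[StateLabel, int]
    time_s: dict[StateLabel, float]
    time_min: dict[StateLabel, float]
    time_pct: dict[StateLabel, float]
    bout_count: dict[StateLabel, int]
    mean_bout_duration_s: dict[StateLabel, float | None]


@dataclass(frozen=True)
class BoutHistogram:
    """Bout counts in duration bins; first bin is open below, last open above.

    With edges (e1..ek) the bins are [0, e1), [e1, e2), ..., [ek, inf):
    k+1 counts in total.
    """

    edges_s: tuple[float, ...]
    counts: np.ndarray

    @property
    def n_bouts(self) -> int:
        return int(self.counts.sum())


def _in_cyclic_interval(zt_h: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Membership of ZT hours (mod 24) in the half-open cyclic interval [lo, hi)."""
    z = np.asarray(zt_h) % 24.0
    lo, hi = lo % 24.0, hi % 24.0
    if lo == hi:  # degenerate: full cycle
        return np.ones_like(z, dtype=bool)
    if lo < hi:
        return (z >= lo) & (z < hi)
    return (z >= lo) | (z < hi)


# ---------------------------------------------------------------------------
# rescoring
# ---------------------------------------------------------------------------

def apply_scoring_rules(h: Hypnogram, max_passes: int = 10) -> Hypnogram:
    """Apply the REM rescoring rules and return a cleaned hypnogram.

    Rule 2 is applied first to whole contiguous REM runs whose first epoch
    directly follows Wake (the entire sleep-onset REM period is rescored as
    Wake), then rule 1 rescoring isolated single REM epochs to the previous
    epoch's state; the pair is iterated to a fixpoint.  A REM run at the very
    start of the recording has no previous state and is conservatively
    rescored as Wake with a logged warning.

    The result is idempotent: it contains no single-epoch REM run and no REM
    epoch whose immediately preceding epoch is Wake.  Epoch count is
    conserved; non-REM epochs are only changed where a rule produces them.
    """
    labels = h.labels.copy()
    for _ in range(max_passes):
        changed = False
        runs = _run_lengths(labels)
        # rule 2: REM run directly after WAKE -> rescored as WAKE
        for state, start, length in runs:
            if state != StateLabel.REM.value:
                continue
            if start == 0:
                logger.warning(
                    "recording begins with a REM run (%d epochs); no previous "
                    "state exists — rescoring the leading run as Wake", length)
                labels[start:start + length] = StateLabel.WAKE.value
                changed = True
            elif labels[start - 1] == StateLabel.WAKE.value:
                labels[start:start + length] = StateLabel.WAKE.value
                changed = True
        # rule 1: isolated single REM epoch -> previous epoch's state
        runs = _run_lengths(labels)
        for state, start, length in runs:
            if state == StateLabel.REM.value and length == 1 and start > 0:
                labels[start] = labels[start - 1]
                changed = True
        if not changed:
            break
    return replace(h, labels=labels)


def _run_lengths(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal same-value runs as (value, start, length), in order."""
    n = labels.size
    if n == 0:
        return []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# bouts
# ---------------------------------------------------------------------------

def detect_bouts(h: Hypnogram) -> list[Bout]:
    """Detect all bouts: maximal same-state runs of length >= 2, in order.

    The bout's light/dark phase is assigned from its onset epoch's ZT; bouts
    spanning the phase boundary are not split, which makes light- and
    dark-phase bout counts exactly additive.
    """
    phases = h.phase_of_epochs()
    bouts = []
    for state, start, length in _run_lengths(h.labels):
        if length >= 2:
            bouts.append(Bout(StateLabel(state), start, length, h.epoch_s,
                              Phase(phases[start])))
    return bouts


# ---------------------------------------------------------------------------
# windows & time in state
# ---------------------------------------------------------------------------

def epoch_window_mask(h: Hypnogram, window) -> np.ndarray:
    """Boolean epoch mask for a window spec.

    ``window`` may be ``"H24"`` (all epochs), ``"LIGHT"``/``"DARK"`` (by each
    epoch's onset ZT against the LD boundaries), or an explicit ``(lo_h,
    hi_h)`` ZT-hour interval, half-open and cyclic (``lo > hi`` wraps past
    midnight of the ZT clock).
    """
    if isinstance(window, str):
        w = window.upper()
        if w == "H24":
            return np.ones(h.n_epochs, dtype=bool)
        if w == "LIGHT":
            return h.phase_of_epochs() == Phase.LIGHT.value
        if w == "DARK":
            return h.phase_of_epochs() == Phase.DARK.value
        raise ValueError(f"unknown window {window!r}")
    lo, hi = window
    return _in_cyclic_interval(h.zt_hours(), lo, hi)


def time_in_state(h: Hypnogram, window="H24") -> dict[StateLabel, dict[str, float]]:
    """Time per state within a window: epoch count, minutes and percentage.

    Every epoch is counted exactly once — singleton runs included; time in
    state is independent of the bout definition.  Percentages over the three
    states sum to 100 (exactly, in rational arithmetic on the epoch counts;
    see :func:`state_fractions_exact`).
    """
    mask = epoch_window_mask(h, window)
    total = int(mask.sum())
    if total == 0:
        raise ValueError(f"window {window!r} contains no epochs")
    out = {}
    for s in StateLabel:
        c = int(((h.labels == s.value) & mask).sum())
        out[s] = {
            "n_epochs": c,
            "time_s": c * h.epoch_s,
            "time_min": c * h.epoch_s / 60.0,
            "time_pct": 100.0 * c / total,
        }
    return out


def state_fractions_exact(h: Hypnogram, window="H24") -> dict[StateLabel, Fraction]:
    """Per-state share of the window as exact rationals (sum is exactly 1)."""
    mask = epoch_window_mask(h, window)
    total = int(mask.sum())
    if total == 0:
        raise ValueError(f"window {window!r} contains no epochs")
    return {s: Fraction(int(((h.labels == s.value) & mask).sum()), total)
            for s in StateLabel}


def hourly_profile(h: Hypnogram, extras: dict[str, np.ndarray] | None = None):
    """Per-ZT-hour state percentages (multi-day recordings pool by ZT hour).

    Returns a pandas DataFrame indexed by ZT hour 0..23 with columns
    ``wake_pct``, ``nrem_pct``, ``rem_pct``, ``n_epochs`` and ``partial``
    (True where the hour holds a non-integral number of full-day's worth of
    epochs — an edge hour of a recording that does not cover whole days).
    Optional ``extras`` maps a column name to a per-epoch series averaged the
    same way.
    """
    import pandas as pd

    if h.duration_s < 3600:
        raise ValueError("recording must cover at least one hour")
    hour = np.floor(h.zt_hours()).astype(int) % 24
    per_hour_full = int(round(3600 / h.epoch_s))
    rows = []
    for zt in range(24):
        m = hour == zt
        n = int(m.sum())
        if n == 0:
            rows.append({"zt_hour": zt, "wake_pct": np.nan, "nrem_pct": np.nan,
                         "rem_pct": np.nan, "n_epochs": 0, "partial": True})
            continue
        row = {"zt_hour": zt, "n_epochs": n, "partial": n % per_hour_full != 0}
        for s, col in zip(StateLabel, ("wake_pct", "nrem_pct", "rem_pct")):
            row[col] = 100.0 * int(((h.labels == s.value) & m).sum()) / n
        if extras:
            for name, series in extras.items():
                row[name] = float(np.asarray(series)[m].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("zt_hour")


# ---------------------------------------------------------------------------
# bout statistics
# ---------------------------------------------------------------------------

def _bouts_in_window(bouts: Sequence[Bout], h: Hypnogram, window) -> list[Bout]:
    mask = epoch_window_mask(h, window)
    return [b for b in bouts if mask[b.onset_epoch]]


def bout_stats(bouts: Sequence[Bout], h: Hypnogram, window="H24"
               ) -> dict[StateLabel, dict[str, float | None]]:
    """Bout count and mean bout duration per state within a window.

    A bout belongs to the window of its onset epoch.  Mean duration is None
    (missing, never 0) where the count is 0.
    """
    sel = _bouts_in_window(bouts, h, window)
    out = {}
    for s in StateLabel:
        durs = [b.duration_s for b in sel if b.state == s]
        out[s] = {
            "bout_count": len(durs),
            "mean_bout_duration_s": (sum(durs) / len(durs)) if durs else None,
        }
    return out


def wake_bout_histogram(bouts: Sequence[Bout],
                        edges_s: Sequence[float] = DEFAULT_HISTOGRAM_EDGES_S,
                        state: StateLabel = StateLabel.WAKE) -> BoutHistogram:
    """Histogram of bout durations with half-open bins [e_i, e_{i+1}).

    Default edges give bins <60, 60-100, 100-140, 140-180, 180-220, 220-260
    and >260 seconds; a duration equal to an edge falls in the bin to its
    right (60 s counts as 60-100 s).  Total count is conserved.
    """
    edges = tuple(float(e) for e in edges_s)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("histogram edges must be strictly increasing")
    durs = np.array([b.duration_s for b in bouts if b.state == state], dtype=float)
    full_edges = np.concatenate(([0.0], edges, [np.inf]))
    counts = np.histogram(durs, bins=full_edges)[0] if durs.size else \
        np.zeros(len(edges) + 1, dtype=int)
    return BoutHistogram(edges, counts.astype(int))


def summarize_architecture(h: Hypnogram, windows=("H24", "LIGHT", "DARK"),
                           rescored: bool = True) -> dict[str, ArchitectureSummary]:
    """Full architecture summary (time + bouts) for each requested window."""
    hh = apply_scoring_rules(h) if rescored else h
    bouts = detect_bouts(hh)
    out = {}
    for w in windows:
        tis = time_in_state(hh, w)
        bs = bout_stats(bouts, hh, w)
        key = w if isinstance(w, str) else f"ZT{w[0]:g}-{w[1]:g}"
        out[key] = ArchitectureSummary(
            window=key,
            n_epochs={s: tis[s]["n_epochs"] for s in StateLabel},
            time_s={s: tis[s]["time_s"] for s in StateLabel},
            time_min={s: tis[s]["time_min"] for s in StateLabel},
            time_pct={s: tis[s]["time_pct"] for s in StateLabel},
            bout_count={s: bs[s]["bout_count"] for s in StateLabel},
            mean_bout_duration_s={s: bs[s]["mean_bout_duration_s"] for s in StateLabel},
        )
    return out
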