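"""Perturbation protocols: sleep-deprivation rebound and the murine MSLT.

The sleep-deprivation (SD) protocol keeps the animal awake for 6 h starting
at lights-on (ZT0-6) and scores the recovery-sleep (RS) opportunity ZT6-11
against a baseline day: hourly NREM/REM minutes, cumulative NREM over the RS
window, and dark-phase REM (REM recovery in mice is typically delayed into
the dark phase).

The murine Multiple Sleep Latency Test (MSLT) gives five 20-min nap
opportunities and scores, per nap, the latency to the first valid bout
(>= 2 epochs) of NREM and of REM sleep plus the accumulated minutes of
each; a nap without a qualifying bout is censored at the nap duration.
Latency is measured to the first epoch of the qualifying bout — onset-
anchored latency, the sleep-field convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hypnogram import (Hypnogram, StateLabel, apply_scoring_rules,
                        detect_bouts, epoch_window_mask, time_in_state)

logger = logging.getLogger(__name__)

__all__ = ["SDProtocol", "MSLTProtocol", "ReboundResult", "NapScore",
           "MSLTResult", "rebound_analysis", "mslt_score"]


@dataclass(frozen=True)
class SDProtocol:
    """Sleep-deprivation protocol windows, in ZT hours."""

    sd_start_zt_h: float = 0.0
    sd_duration_h: float = 6.0
    rs_window: tuple[float, float] = (6.0, 11.0)
    followup_dark_window: tuple[float, float] = (12.0, 24.0)

    def __post_init__(self):
        sd_end = self.sd_start_zt_h + self.sd_duration_h
        if not (sd_end <= self.rs_window[0] < self.rs_window[1]
                <= self.followup_dark_window[0] < self.followup_dark_window[1] <= 24):
            raise ValueError("SD, RS and dark follow-up windows must be "
                             "ordered, non-overlapping and within 24 h")

    @property
    def sd_window(self) -> tuple[float, float]:
        return (self.sd_start_zt_h, self.sd_start_zt_h + self.sd_duration_h)


@dataclass(frozen=True)
class MSLTProtocol:
    """Nap-opportunity schedule: (start_zt_s, duration_s) per nap."""

    nap_windows: tuple[tuple[float, float], ...] = tuple(
        (7200.0 + i * 7200.0, 1200.0) for i in range(5))

    def __post_init__(self):
        prev_end = -np.inf
        for start, dur in self.nap_windows:
            if dur <= 0:
                raise ValueError("nap duration must be positive")
            if start < prev_end:
                raise ValueError("nap windows must be ordered and non-overlapping")
            prev_end = start + dur


@dataclass(frozen=True)
class ReboundResult:
    """Baseline vs SD-day comparison of recovery sleep."""

    hourly_nrem_min: dict[str, dict[int, float]]
    hourly_rem_min: dict[str, dict[int, float]]
    cumulative_rs_nrem_min: dict[str, float]
    dark_rem_min: dict[str, float]
    hourly_nrem_diff_min: dict[int, float]
    hourly_rem_diff_min: dict[int, float]
    normalized_swa: dict[int, float | None] | None = None


@dataclass(frozen=True)
class NapScore:
    """Per-nap MSLT metrics; latencies censored at the nap duration."""

    nap_index: int
    latency_to_nrem_s: float
    nrem_censored: bool
    latency_to_rem_s: float
    rem_censored: bool
    nrem_min: float
    rem_min: float


@dataclass(frozen=True)
class MSLTResult:
    naps: tuple[NapScore, ...]

    def mean_latency_s(self, state: StateLabel) -> float:
        key = "latency_to_nrem_s" if state == StateLabel.NREM else "latency_to_rem_s"
        return float(np.mean([getattr(n, key) for n in self.naps]))


def _hourly_state_minutes(h: Hypnogram, state: StateLabel,
                          hours=range(24)) -> dict[int, float]:
    out = {}
    for zt in hours:
        tis = time_in_state(h, (float(zt), float(zt + 1)))
        out[int(zt)] = tis[state]["time_min"]
    return out


def _require_full_day(h: Hypnogram, name: str):
    if h.duration_s < 86400 or h.zt_start_s != 0:
        raise ValueError(f"{name} hypnogram must cover ZT0-24 of one day "
                         f"(got {h.duration_s / 3600:.2f} h from "
                         f"ZT {h.zt_start_s / 3600:.2f})")


def rebound_analysis(baseline_h: Hypnogram, sd_h: Hypnogram,
                     proto: SDProtocol = SDProtocol(),
                     normalized_swa: dict[int, float | None] | None = None
                     ) -> ReboundResult:
    """Score recovery sleep on an SD day against a baseline day.

    Both hypnograms must cover ZT0-24 of their respective days.  A warning is
    logged if more than 5% of the SD window on the SD day is scored as sleep
    (imperfect deprivation compliance).  Differences are SD day minus
    baseline.  An hourly normalized SWA series (from
    :func:`sleeparch.spectral.nrem_delta_timecourse` +
    :func:`sleeparch.spectral.normalize_to_baseline`) may be attached.
    """
    _require_full_day(baseline_h, "baseline")
    _require_full_day(sd_h, "SD-day")
    sd_tis = time_in_state(sd_h, proto.sd_window)
    sleep_pct = sd_tis[StateLabel.NREM]["time_pct"] + sd_tis[StateLabel.REM]["time_pct"]
    if sleep_pct > 5.0:
        logger.warning("%.1f%% of the SD window is scored as sleep; "
                       "deprivation may not have been enforced", sleep_pct)

    hourly_n = {"baseline": _hourly_state_minutes(baseline_h, StateLabel.NREM),
                "sd": _hourly_state_minutes(sd_h, StateLabel.NREM)}
    hourly_r = {"baseline": _hourly_state_minutes(baseline_h, StateLabel.REM),
                "sd": _hourly_state_minutes(sd_h, StateLabel.REM)}
    rs_hours = range(int(proto.rs_window[0]), int(proto.rs_window[1]))
    cum = {day: float(sum(hourly_n[day][zt] for zt in rs_hours))
           for day in ("baseline", "sd")}
    dark = {day: time_in_state(hh, proto.followup_dark_window)[StateLabel.REM]["time_min"]
            for day, hh in (("baseline", baseline_h), ("sd", sd_h))}
    return ReboundResult(
        hourly_nrem_min=hourly_n,
        hourly_rem_min=hourly_r,
        cumulative_rs_nrem_min=cum,
        dark_rem_min=dark,
        hourly_nrem_diff_min={zt: hourly_n["sd"][zt] - hourly_n["baseline"][zt]
                              for zt in range(24)},
        hourly_rem_diff_min={zt: hourly_r["sd"][zt] - hourly_r["baseline"][zt]
                             for zt in range(24)},
        normalized_swa=normalized_swa,
    )


def mslt_score(h: Hypnogram, proto: MSLTProtocol = MSLTProtocol(),
               check_rescoring: bool = True) -> MSLTResult:
    """Score each nap opportunity of an MSLT hypnogram.

    Latency to a state = time from nap start to the onset of the first bout
    (>= 2 consecutive epochs) of that state beginning inside the nap; naps
    without such a bout get latency = nap duration with a censoring flag.
    Accumulation counts every epoch of the state inside the nap, singletons
    included.  With ``check_rescoring`` the labels are compared against their
    rescored version and violations of the REM rules are logged.
    """
    if check_rescoring and not np.array_equal(apply_scoring_rules(h).labels, h.labels):
        logger.warning("hypnogram is not a fixpoint of the rescoring rules "
                       "(singleton REM or wake-to-REM transitions present); "
                       "scoring proceeds on the labels as given")
    naps = []
    for i, (start_s, dur_s) in enumerate(proto.nap_windows):
        e0 = int(round((start_s - h.zt_start_s) / h.epoch_s))
        n_ep = int(round(dur_s / h.epoch_s))
        if e0 < 0 or e0 + n_ep > h.n_epochs:
            raise ValueError(f"nap {i} (ZT {start_s / 3600:.2f} h, {dur_s:.0f} s) "
                             "extends past the recording")
        sub = Hypnogram(h.labels[e0:e0 + n_ep], h.epoch_s,
                        (h.zt_start_s + e0 * h.epoch_s) % 86400.0,
                        h.lights_on_h, h.lights_off_h)
        bouts = detect_bouts(sub)
        score = {"nap_index": i}
        for state, tag in ((StateLabel.NREM, "nrem"), (StateLabel.REM, "rem")):
            first = next((b for b in bouts if b.state == state), None)
            if first is None:
                score[f"latency_to_{tag}_s"] = float(dur_s)
                score[f"{tag}_censored"] = True
                logger.info("nap %d: no %s bout; latency censored at %.0f s",
                            i, state.name, dur_s)
            else:
                score[f"latency_to_{tag}_s"] = first.onset_epoch * h.epoch_s
                score[f"{tag}_censored"] = False
            score[f"{tag}_min"] = int((sub.labels == state.value).sum()) * h.epoch_s / 60.0
        naps.append(NapScore(**score))
    return MSLTResult(tuple(naps))
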