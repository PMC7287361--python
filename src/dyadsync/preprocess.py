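"""Preprocessing: downsampling, standardisation and trial-level SCR scoring.

Two consumers sit downstream. Cross-recurrence analysis takes each learning
phase's demonstrator and observer traces downsampled to 8 Hz and z-scored.
The regression models take trial-level skin-conductance response (SCR)
amplitudes, scored from the raw (µS) trace with a conventional
baseline-to-peak rule and a log(1+x) transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import EventSchedule, Trial
from .traces import DegenerateSignalError, SignalTrace

__all__ = [
    "PreprocessConfig",
    "downsample",
    "zscore",
    "crqa_ready",
    "score_scr",
    "score_phase",
    "ucs_responses",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["dyad_id", "block", "phase", "trial_index", "cs_code",
                 "amplitude_raw", "amplitude_tx"]

_TRANSFORMS = {
    "log1p": np.log1p,
    "sqrt": np.sqrt,
    "none": lambda x: x,
}


@dataclass(frozen=True)
class PreprocessConfig:
    """Scoring and resampling settings.

    ``scr_window`` is the post-onset interval searched for the response peak
    and ``baseline_window`` the pre-onset interval (relative seconds) whose
    mean is subtracted; both are conventional event-related EDA choices.
    """

    target_hz: float = 8.0
    scr_window: tuple[float, float] = (0.5, 4.5)
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    transform: str = "log1p"

    def __post_init__(self) -> None:
        if self.scr_window[0] >= self.scr_window[1]:
            raise ValueError("scr_window must be increasing")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ValueError("baseline_window must be increasing")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.target_hz <= 0:
            raise ValueError("target_hz must be positive")

    def apply_transform(self, x):
        return _TRANSFORMS[self.transform](x)


def downsample(trace: SignalTrace, target_hz: float) -> SignalTrace:
    """Resample to ``target_hz`` by non-overlapping block averaging.

    Block means act as a crude anti-alias filter, which decimation would
    not. The source rate must be an integer multiple of the target; the
    trailing remainder (< one output sample) is dropped.
    """
    if target_hz > trace.fs:
        raise ValueError(
            f"cannot downsample {trace.fs} Hz trace to {target_hz} Hz")
    factor = trace.fs / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"source rate {trace.fs} Hz is not an integer multiple of "
            f"{target_hz} Hz")
    factor = int(round(factor))
    if factor == 1:
        return trace.with_values(trace.values.copy())
    n_out = len(trace) // factor
    blocks = trace.values[: n_out * factor].reshape(n_out, factor)
    return trace.with_values(blocks.mean(axis=1), fs=target_hz)


def zscore(trace: SignalTrace) -> SignalTrace:
    """Standardise to mean 0, sample SD 1 (ddof=1).

    Raises :class:`DegenerateSignalError` on constant input so broken
    fixtures surface instead of silently propagating zeros.
    """
    x = trace.values
    if len(x) < 2:
        raise DegenerateSignalError("need at least 2 samples to z-score")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError(
            f"zero-variance trace {trace.key()} cannot be z-scored")
    return trace.with_values((x - x.mean()) / sd)


def crqa_ready(trace: SignalTrace, cfg: PreprocessConfig | None = None) -> SignalTrace:
    """Convenience: downsample to the CRQA rate then z-score."""
    cfg = cfg or PreprocessConfig()
    return zscore(downsample(trace, cfg.target_hz))


def _window_mean_max(trace: SignalTrace, start: float, stop: float,
                     what: str) -> tuple[float, float]:
    i0 = int(np.floor((start - trace.t0) * trace.fs))
    i1 = int(np.ceil((stop - trace.t0) * trace.fs))
    if i0 < 0 or i1 > len(trace):
        raise ValueError(
            f"{what}: window [{start:.2f}, {stop:.2f}] s falls outside trace "
            f"{trace.key()} spanning [{trace.t0:.2f}, {trace.t0 + trace.duration:.2f}] s")
    seg = trace.values[i0:i1]
    return float(seg.mean()), float(seg.max())


def score_scr(trace: SignalTrace, onset: float,
              cfg: PreprocessConfig | None = None, label: str = "trial") -> float:
    """Score one event-related SCR amplitude in µS.

    Amplitude = max of the trace inside ``scr_window`` after ``onset`` minus
    the mean over ``baseline_window`` before it, floored at zero (an SCR is
    a rise; anything else scores 0).
    """
    cfg = cfg or PreprocessConfig()
    base_mean, _ = _window_mean_max(
        trace, onset + cfg.baseline_window[0], onset + cfg.baseline_window[1],
        label)
    _, peak = _window_mean_max(
        trace, onset + cfg.scr_window[0], onset + cfg.scr_window[1], label)
    return max(0.0, peak - base_mean)


def score_phase(trace: SignalTrace, schedule: EventSchedule,
                cfg: PreprocessConfig | None = None,
                phase: str | None = None) -> pd.DataFrame:
    """Score every CS presentation of one phase into a trial table.

    Returns one row per presentation with deviation-coded CS (+0.5 CS+,
    −0.5 CS−), the raw µS amplitude and its transform.
    """
    cfg = cfg or PreprocessConfig()
    phase = phase or trace.phase
    trials = schedule.phase_trials(phase)
    if not trials:
        raise ValueError(f"no {phase} trials in schedule block {schedule.block}")
    rows = []
    for tr in trials:
        amp = score_scr(trace, tr.onset, cfg,
                        label=f"dyad {trace.dyad_id} block {schedule.block} "
                              f"{phase} trial {tr.index}")
        rows.append({
            "dyad_id": trace.dyad_id,
            "block": schedule.block,
            "phase": phase,
            "trial_index": tr.index,
            "cs_code": tr.cs_code,
            "amplitude_raw": amp,
            "amplitude_tx": float(cfg.apply_transform(amp)),
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def ucs_responses(observer_trace: SignalTrace, schedule: EventSchedule,
                  cfg: PreprocessConfig | None = None) -> tuple[pd.DataFrame, float]:
    """Observer responses to the social UCS (demonstrator receiving shock).

    Scores one amplitude per learning-phase shock event, with the windows
    anchored at shock delivery time rather than CS onset. Returns the
    per-event table and the mean amplitude.
    """
    cfg = cfg or PreprocessConfig()
    shocks = [t for t in schedule.learning_trials if t.shock]
    if not shocks:
        raise ValueError(
            f"schedule block {schedule.block} has no learning-phase shocks")
    rows = []
    for tr in shocks:
        amp = score_scr(observer_trace, tr.shock_time, cfg,
                        label=f"dyad {observer_trace.dyad_id} block "
                              f"{schedule.block} shock trial {tr.index}")
        rows.append({"dyad_id": observer_trace.dyad_id,
                     "block": schedule.block,
                     "trial_index": tr.index,
                     "amplitude_raw": amp,
                     "amplitude_tx": float(cfg.apply_transform(amp))})
    table = pd.DataFrame(rows)
    return table, float(table["amplitude_raw"].mean())
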