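"""Uniformly sampled phasic skin-conductance traces.

A :class:`SignalTrace` is the unit of data flowing through the pipeline: one
person's phasic electrodermal signal for one phase (learning or testing) of
one experimental block, sampled at a fixed rate, with identity metadata
(dyad, role, block, phase) attached so traces can be grouped and matched to
event schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SignalTrace", "DegenerateSignalError"]


class DegenerateSignalError(ValueError):
    """Raised when an operation receives a constant (zero-variance) trace."""


@dataclass
class SignalTrace:
    """One uniformly sampled phasic skin-conductance series.

    Parameters
    ----------
    values : ndarray
        Conductance samples in microsiemens (or z-units after scaling).
    fs : float
        Sampling rate in Hz.
    dyad_id : str
        Identifier of the dyad the trace belongs to.
    role : str
        ``"demonstrator"`` or ``"observer"``.
    block : int
        1-based block index.
    phase : str
        ``"learning"`` or ``"testing"``.
    t0 : float
        Time of the first sample in seconds from phase start (normally 0).
    """

    values: np.ndarray
    fs: float
    dyad_id: str = ""
    role: str = ""
    block: int = 1
    phase: str = ""
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SignalTrace values must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from phase start."""
        return self.t0 + np.arange(len(self)) / self.fs

    def with_values(self, values: np.ndarray, fs: float | None = None) -> "SignalTrace":
        """Copy of this trace with new samples (and optionally a new rate)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       fs=self.fs if fs is None else fs)

    def crop(self, duration_s: float) -> "SignalTrace":
        """Trace truncated to its first ``duration_s`` seconds."""
        n = int(round(duration_s * self.fs))
        if n < 1 or n > len(self):
            raise ValueError(
                f"cannot crop trace of {self.duration:.1f}s to {duration_s}s")
        return self.with_values(self.values[:n])

    def key(self) -> tuple:
        return (self.dyad_id, self.role, self.block, self.phase)
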