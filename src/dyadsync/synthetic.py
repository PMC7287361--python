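"""Synthetic dyadic observational-conditioning experiments.

Generates skin-conductance data for demonstrator–observer pairs with the
standard observational threat-learning design: each block is a learning phase
(six alternating CS+ / CS− presentations of 6 s, variable 10–16 s inter-trial
interval, four of the six CS+ trials ending in a shock to the demonstrator)
followed by a testing phase (seven presentations per CS, only the final CS+
shocked — now to the observer). Roles reverse halfway through the blocks.

The generative model embeds a known ground truth so downstream stages have a
parameter-recovery surface:

* phasic skin conductance is a sum of event-locked SCR kernels (peak-
  normalised differences of exponentials), spontaneous Poisson-process SCRs
  and Gaussian measurement noise;
* demonstrator→observer coupling ``kappa`` in [0, 1] mixes the observer's
  event-response amplitudes with the demonstrator's (delayed by ``lag``) and
  shrinks the observer's idiosyncratic response-latency jitter, so larger
  ``kappa`` means tighter physiological synchrony;
* the observer's testing-phase CS-onset response amplitudes follow
  ``beta0 + (beta_cs_base + learning_gain * kappa) * cs_code * exp(-extinction_rate * k)``
  with deviation-coded CS (``cs_code`` ±0.5) and within-CS presentation index
  ``k``, so the coupling→learning link is a known linear effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .traces import SignalTrace

__all__ = [
    "DesignConfig",
    "SCRKernel",
    "CouplingConfig",
    "Trial",
    "EventSchedule",
    "EventResponse",
    "BlockRecord",
    "DyadRecord",
    "DyadDataset",
    "default_kernels",
    "make_schedule",
    "scr_kernel_eval",
    "synth_demonstrator_trace",
    "synth_observer_trace",
    "generate_dataset",
]

#: Quiet lead-in before the first trial onset, seconds (room for a baseline
#: window), and tail after the last event (room for SCR decay + score window).
PHASE_LEAD_IN_S = 5.0
PHASE_TAIL_S = 12.0


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design constants.

    Defaults reproduce the live observational-conditioning protocol:
    69 same-sex dyads, 4 blocks, 6 alternating presentations of each CS
    (6 s each, 10–16 s ITI) in the learning phase with 4 of 6 CS+ shocked,
    and 7 presentations per CS in the testing phase.
    """

    n_dyads: int = 69
    n_blocks: int = 4
    n_cs_each_learning: int = 6
    n_shocked_csplus: int = 4
    cs_duration: float = 6.0
    iti_range: tuple[float, float] = (10.0, 16.0)
    n_cs_each_testing: int = 7
    sample_rate: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shocked_csplus > self.n_cs_each_learning:
            raise ValueError(
                f"n_shocked_csplus ({self.n_shocked_csplus}) cannot exceed "
                f"n_cs_each_learning ({self.n_cs_each_learning})")
        lo, hi = self.iti_range
        if lo > hi:
            raise ValueError(f"iti_range min {lo} exceeds max {hi}")
        if self.sample_rate < 8:
            raise ValueError("sample_rate must be at least 8 Hz")
        if min(self.n_dyads, self.n_blocks, self.n_cs_each_learning,
               self.n_cs_each_testing) < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SCRKernel:
    """Canonical phasic skin-conductance response shape.

    A peak-normalised difference of exponentials (Bateman form): zero before
    ``latency``, then ``amplitude * norm * (exp(-t/tau_decay) - exp(-t/tau_rise))``
    with ``norm`` chosen so the maximum equals ``amplitude`` (in µS).
    """

    amplitude: float = 1.0
    tau_rise: float = 0.75
    tau_decay: float = 2.5
    latency: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum, seconds after event onset."""
        tr, td = self.tau_rise, self.tau_decay
        return self.latency + tr * td / (td - tr) * math.log(td / tr)

    @property
    def _norm(self) -> float:
        tp = self.peak_time - self.latency
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))

    @property
    def support(self) -> float:
        """Duration after which the kernel is negligible (<0.1% of peak)."""
        return self.latency + 8.0 * self.tau_decay


def scr_kernel_eval(kernel: SCRKernel, t: float | np.ndarray) -> np.ndarray:
    """Evaluate an SCR kernel at time(s) ``t`` seconds after event onset."""
    t = np.asarray(t, dtype=float)
    s = t - kernel.latency
    out = np.zeros_like(t)
    pos = s > 0
    sp = s[pos]
    out[pos] = kernel.amplitude * kernel._norm * (
        np.exp(-sp / kernel.tau_decay) - np.exp(-sp / kernel.tau_rise))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CouplingConfig:
    """Demonstrator→observer coupling and nuisance parameters.

    ``kappa`` is the fraction of the observer's event-response drive copied
    from the demonstrator; ``learning_gain`` is the slope linking ``kappa``
    to the observer's testing-phase CS differentiation (µS per unit kappa on
    the deviation-coded CS contrast).
    """

    kappa: float = 0.5
    lag: float = 1.0                  # s, observer responses trail demonstrator
    spontaneous_rate: float = 6.0     # nonspecific SCRs per minute
    noise_sd: float = 0.10            # µS measurement noise (at 8 Hz band)
    learning_gain: float = 0.5        # µS differentiation per unit kappa
    extinction_rate: float = 0.1      # per unreinforced test presentation
    amp_jitter_sd: float = 0.4        # log-sd of mean-one amplitude jitter
    response_prob: float = 0.55       # chance an independent SCR is emitted
    spont_jitter_sd: float = 0.8      # log-sd of spontaneous-SCR amplitudes
    latency_jitter_sd: float = 4.0    # s, latency of independent responses
    latency_jitter_min: float = 0.15  # s, latency jitter of mirrored copies
    lag_warp_sd: float = 1.0          # s, SD of the slowly wandering lag
    lag_warp_tau: float = 30.0        # s, time constant of the lag wander
    episode_tau: float = 90.0         # s, persistence of the coupling state
    drift_sd: float = 0.25            # µS stationary SD of slow OU drift
    drift_tau: float = 10.0           # s, OU time constant of the drift
    beta0: float = 0.5                # µS baseline test-phase CS response
    beta_cs_base: float = 0.05        # µS kappa-independent differentiation

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if not 0.0 < self.response_prob <= 1.0:
            raise ValueError("response_prob must lie in (0, 1]")
        for name in ("lag", "spontaneous_rate", "noise_sd", "extinction_rate",
                     "amp_jitter_sd", "latency_jitter_sd",
                     "latency_jitter_min", "spont_jitter_sd", "drift_sd",
                     "drift_tau", "lag_warp_sd", "lag_warp_tau",
                     "episode_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Trial:
    """One CS presentation."""

    phase: str                 # "learning" | "testing"
    index: int                 # 1-based within phase
    cs: str                    # "plus" | "minus"
    onset: float               # s from phase start
    duration: float
    shock: bool = False
    shock_time: float | None = None

    @property
    def cs_code(self) -> float:
        """Deviation code: +0.5 for CS+, −0.5 for CS−."""
        return 0.5 if self.cs == "plus" else -0.5

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class EventSchedule:
    """Ordered trial records for one block (learning then testing phase)."""

    block: int
    trials: list[Trial]

    def phase_trials(self, phase: str) -> list[Trial]:
        return [t for t in self.trials if t.phase == phase]

    @property
    def learning_trials(self) -> list[Trial]:
        return self.phase_trials("learning")

    @property
    def testing_trials(self) -> list[Trial]:
        return self.phase_trials("testing")

    def phase_duration(self, phase: str) -> float:
        trials = self.phase_trials(phase)
        return max(t.offset for t in trials) + PHASE_TAIL_S

    def validate(self, design: DesignConfig) -> None:
        """Raise if any structural invariant of the design is violated."""
        for phase in ("learning", "testing"):
            trials = self.phase_trials(phase)
            for a, b in zip(trials, trials[1:]):
                if b.onset < a.offset:
                    raise ValueError(f"overlapping trials in {phase} phase")
                if b.index != a.index + 1:
                    raise ValueError(f"non-consecutive indices in {phase}")
        learn = self.learning_trials
        n = design.n_cs_each_learning
        if sum(t.cs == "plus" for t in learn) != n or len(learn) != 2 * n:
            raise ValueError("learning phase must hold n CS+ and n CS− trials")
        if any(a.cs == b.cs for a, b in zip(learn, learn[1:])):
            raise ValueError("learning-phase CS valences must alternate")
        if sum(t.shock for t in learn) != design.n_shocked_csplus:
            raise ValueError("wrong number of shocked learning trials")
        if any(t.shock and t.cs != "plus" for t in self.trials):
            raise ValueError("shocks may only occur on CS+ trials")
        test = self.testing_trials
        m = design.n_cs_each_testing
        if sum(t.cs == "plus" for t in test) != m or len(test) != 2 * m:
            raise ValueError("testing phase must hold m CS+ and m CS− trials")
        shocked = [t for t in test if t.shock]
        final_plus = [t for t in test if t.cs == "plus"][-1]
        if len(shocked) != 1 or shocked[0] is not final_plus:
            raise ValueError("exactly the final testing CS+ must be shocked")


def _lay_out(trials: list[tuple[str, bool]], phase: str, design: DesignConfig,
             rng: np.random.Generator) -> list[Trial]:
    """Assign onsets with uniform ITIs to an ordered valence/shock list."""
    lo, hi = design.iti_range
    out, onset = [], PHASE_LEAD_IN_S
    for i, (cs, shock) in enumerate(trials, start=1):
        shock_time = onset + design.cs_duration if shock else None
        out.append(Trial(phase=phase, index=i, cs=cs, onset=onset,
                         duration=design.cs_duration, shock=shock,
                         shock_time=shock_time))
        onset += design.cs_duration + rng.uniform(lo, hi)
    return out


def make_schedule(design: DesignConfig, block_index: int,
                  rng: np.random.Generator) -> EventSchedule:
    """Draw one block's trial schedule.

    Learning phase: strictly alternating CS+/CS− (first valence random),
    with ``n_shocked_csplus`` of the CS+ trials shocked, chosen uniformly
    without replacement; shocks land at CS offset. Testing phase: a random
    order of the 2·``n_cs_each_testing`` presentations, with a single shock
    on the final CS+ presentation.
    """
    first = rng.choice(["plus", "minus"])
    other = "minus" if first == "plus" else "plus"
    valences = [first, other] * design.n_cs_each_learning
    shocked = set(rng.choice(design.n_cs_each_learning,
                             size=design.n_shocked_csplus, replace=False))
    plus_seen = 0
    learn: list[tuple[str, bool]] = []
    for cs in valences:
        shock = False
        if cs == "plus":
            shock = plus_seen in shocked
            plus_seen += 1
        learn.append((cs, shock))

    labels = ["plus"] * design.n_cs_each_testing + ["minus"] * design.n_cs_each_testing
    order = rng.permutation(len(labels))
    test_cs = [labels[i] for i in order]
    last_plus = max(i for i, cs in enumerate(test_cs) if cs == "plus")
    test = [(cs, i == last_plus) for i, cs in enumerate(test_cs)]

    trials = _lay_out(learn, "learning", design, rng)
    trials += _lay_out(test, "testing", design, rng)
    sched = EventSchedule(block=block_index, trials=trials)
    sched.validate(design)
    return sched


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventResponse:
    """One event-locked SCR as actually emitted into a trace."""

    time: float        # s from phase start (response drive onset)
    amplitude: float   # µS peak
    kind: str          # "cs_plus" | "cs_minus" | "shock" | "spont"
    trial_index: int | None = None


def default_kernels() -> dict[str, SCRKernel]:
    """Per-event-type SCR kernels; the shock response dominates."""
    return {
        "shock": SCRKernel(amplitude=0.8),
        "cs_plus": SCRKernel(amplitude=0.3),
        "cs_minus": SCRKernel(amplitude=0.3),
        "spont": SCRKernel(amplitude=0.4),
    }


def _jitter(rng: np.random.Generator, sd: float, size=None) -> np.ndarray:
    """Mean-one lognormal multiplicative jitter."""
    if sd == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(-0.5 * sd ** 2, sd, size=size))


def _render(events: Iterable[EventResponse], duration: float, fs: float,
            kernels: dict[str, SCRKernel], noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    """Superimpose event kernels on a noise floor."""
    n = int(round(duration * fs))
    # white noise scaled so block-averaging down to 8 Hz leaves sd ~ noise_sd
    sd = noise_sd * math.sqrt(fs / 8.0)
    sig = rng.normal(0.0, sd, size=n) if noise_sd > 0 else np.zeros(n)
    t = np.arange(n) / fs
    for ev in events:
        k = replace(kernels[ev.kind], amplitude=1.0)
        i0 = max(0, int(math.floor(ev.time * fs)))
        i1 = min(n, int(math.ceil((ev.time + k.support) * fs)) + 1)
        if i1 <= i0:
            continue
        sig[i0:i1] += ev.amplitude * scr_kernel_eval(k, t[i0:i1] - ev.time)
    return sig


def _ou_process(n: int, fs: float, sd: float, tau: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (SD ``sd``, timescale
    ``tau`` seconds)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = math.exp(-1.0 / (fs * tau))
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i]
    return x


def _slow_drift(n: int, fs: float, coupling: CouplingConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Residual slow (imperfectly removed tonic) fluctuation; independent
    per person."""
    return _ou_process(n, fs, coupling.drift_sd, coupling.drift_tau, rng)


def _spontaneous(duration: float, coupling: CouplingConfig,
                 rng: np.random.Generator,
                 amplitude: float) -> list[EventResponse]:
    n = rng.poisson(coupling.spontaneous_rate * duration / 60.0)
    times = np.sort(rng.uniform(0, duration, size=n))
    amps = amplitude * _jitter(rng, coupling.spont_jitter_sd, size=n)
    return [EventResponse(time=float(t), amplitude=float(a), kind="spont")
            for t, a in zip(times, amps)]


def _stimulus_events(trials: Sequence[Trial], kernels: dict[str, SCRKernel],
                     coupling: CouplingConfig,
                     rng: np.random.Generator) -> list[EventResponse]:
    """Event-locked responses of a person who sees/feels the stimuli."""
    events = []
    p = coupling.response_prob
    for tr in trials:
        kind = f"cs_{tr.cs}"
        amp = kernels[kind].amplitude * _jitter(rng, coupling.amp_jitter_sd)
        if rng.random() >= p:
            amp = 0.0        # non-response trial: SCRs are famously sparse
        events.append(EventResponse(tr.onset, float(amp), kind, tr.index))
        if tr.shock:
            amp = kernels["shock"].amplitude * _jitter(rng, coupling.amp_jitter_sd)
            events.append(EventResponse(tr.shock_time, float(amp), "shock",
                                        tr.index))
    return events


def synth_demonstrator_trace(
    schedule: EventSchedule,
    kernels: dict[str, SCRKernel],
    coupling: CouplingConfig,
    rng: np.random.Generator,
    phase: str = "learning",
    sample_rate: float = 32.0,
) -> tuple[SignalTrace, list[EventResponse]]:
    """Demonstrator's phasic trace for one phase, plus its stimulus events.

    During learning the demonstrator responds to every CS onset and receives
    the shocks. During testing the demonstrator sits behind a screen with
    eyes closed, so the trace holds only spontaneous SCRs and noise.

    Returns the trace and the list of stimulus-locked events (the coupling
    substrate handed to :func:`synth_observer_trace`); spontaneous SCRs are
    rendered into the trace but are idiosyncratic, never shared.
    """
    trials = schedule.phase_trials(phase)
    if not trials:
        raise ValueError(f"schedule block {schedule.block} has no {phase} trials")
    duration = schedule.phase_duration(phase)
    if phase == "learning":
        events = _stimulus_events(trials, kernels, coupling, rng)
    else:
        events = []
    events = events + _spontaneous(duration, coupling, rng,
                                   kernels["spont"].amplitude)
    values = _render(events, duration, sample_rate, kernels,
                     coupling.noise_sd, rng)
    drift = _slow_drift(len(values), sample_rate, coupling, rng)
    trace = SignalTrace(values + drift, fs=sample_rate, role="demonstrator",
                        block=schedule.block, phase=phase,
                        meta={"drift": drift})
    return trace, events


def synth_observer_trace(
    demo_events: Sequence[EventResponse],
    schedule: EventSchedule,
    coupling: CouplingConfig,
    kernels: dict[str, SCRKernel],
    rng: np.random.Generator,
    phase: str = "learning",
    sample_rate: float = 32.0,
    demo_drift: np.ndarray | None = None,
) -> SignalTrace:
    """Observer's phasic trace for one phase.

    Learning phase: every demonstrator event — CS-locked, shock-locked and
    nonspecific (spontaneous) arousal alike — is either *mirrored* by the
    observer (probability ``kappa``: same amplitude, delayed by ``lag`` with
    tight ``latency_jitter_min`` timing) or replaced by an *independent*
    response drawn from the same marginal distribution (heavily jittered
    timing, own amplitude, stochastic non-response). At ``kappa = 1`` the
    demonstrator's arousal stream is reproduced event for event; at
    ``kappa = 0`` the observer is an unrelated responder with matched
    single-signal statistics, so coupling is visible only *between* the two
    signals, never from one alone. The slow latent arousal drift is
    likewise mirrored: the observer's drift is ``kappa`` times the
    demonstrator's (delayed by ``lag``, passed as ``demo_drift``) plus
    ``sqrt(1−kappa²)`` of an independent drift, preserving its stationary
    variance. Fully coupled observers (kappa = 1, lag = 0) therefore
    reproduce the demonstrator's event responses and arousal trajectory
    exactly; uncoupled observers respond to the same stimuli with
    independent amplitudes, timing and drift.

    Testing phase: CS-onset response amplitudes follow the learning model
    ``beta0 + (beta_cs_base + learning_gain·kappa)·cs_code·exp(-extinction_rate·k)``
    (``k`` = 0-based within-CS presentation count) with mean-one lognormal
    amplitude jitter, so the observer's CS differentiation carries a known
    linear imprint of the coupling. The single reinforced final CS+ adds a
    shock response (the observer receives that shock).
    """
    kappa = coupling.kappa  # validated by CouplingConfig
    trials = schedule.phase_trials(phase)
    if not trials:
        raise ValueError(f"schedule block {schedule.block} has no {phase} trials")
    duration = schedule.phase_duration(phase)
    events: list[EventResponse] = []

    if phase == "learning":
        # Episodic mirroring: a two-state Markov chain with stationary
        # probability kappa decides, event by event, whether the observer is
        # currently coupled. Coupled events are copied (same amplitude,
        # tight latency); uncoupled ones are replaced by independent
        # responses drawn from the same marginal distribution, so the
        # observer's single-trace statistics do not betray kappa — coupling
        # is visible only between the signals.
        ordered = sorted(demo_events, key=lambda e: e.time)
        coupled = rng.random() < kappa
        prev_t = None
        for ev in ordered:
            if prev_t is not None and coupling.episode_tau > 0:
                p_keep = math.exp(-(ev.time - prev_t) / coupling.episode_tau)
                if rng.random() >= p_keep:
                    coupled = rng.random() < kappa
            elif prev_t is not None:
                coupled = rng.random() < kappa
            prev_t = ev.time
            if coupled:
                jitter_t = rng.normal(0.0, coupling.latency_jitter_min)
                time = max(ev.time, ev.time + coupling.lag + jitter_t)
                events.append(EventResponse(time, ev.amplitude, ev.kind,
                                            ev.trial_index))
                continue
            if ev.kind == "spont":
                # autonomous nonspecific SCR at an unrelated moment
                time = rng.uniform(0.0, duration)
                amp = kernels["spont"].amplitude * _jitter(
                    rng, coupling.spont_jitter_sd)
                events.append(EventResponse(float(time), float(amp), "spont"))
                continue
            amp = kernels[ev.kind].amplitude * _jitter(rng, coupling.amp_jitter_sd)
            if ev.kind != "shock" and rng.random() >= coupling.response_prob:
                amp = 0.0  # independent non-response
            jitter_t = rng.normal(0.0, coupling.latency_jitter_sd)
            time = max(ev.time, ev.time + coupling.lag + jitter_t)
            events.append(EventResponse(time, float(amp), ev.kind,
                                        ev.trial_index))
    else:
        delta = coupling.beta_cs_base + coupling.learning_gain * kappa
        seen = {"plus": 0, "minus": 0}
        for tr in trials:
            k = seen[tr.cs]
            seen[tr.cs] += 1
            mean_amp = coupling.beta0 + delta * tr.cs_code * math.exp(
                -coupling.extinction_rate * k)
            amp = max(0.0, mean_amp) * _jitter(rng, coupling.amp_jitter_sd)
            events.append(EventResponse(tr.onset, float(amp), f"cs_{tr.cs}",
                                        tr.index))
            if tr.shock:
                amp = kernels["shock"].amplitude * _jitter(rng, coupling.amp_jitter_sd)
                events.append(EventResponse(tr.shock_time, float(amp), "shock",
                                            tr.index))

    if phase != "learning":
        events = events + _spontaneous(duration, coupling, rng,
                                       kernels["spont"].amplitude)
    values = _render(events, duration, sample_rate, kernels,
                     coupling.noise_sd, rng)
    own = _slow_drift(len(values), sample_rate, coupling, rng)
    if demo_drift is not None and kappa > 0:
        n = len(values)
        t = np.arange(n) / sample_rate
        # the mirrored trajectory trails by a slowly wandering lag
        if coupling.lag_warp_sd > 0:
            warp = _ou_process(n, sample_rate, coupling.lag_warp_sd,
                               coupling.lag_warp_tau, rng)
        else:
            warp = np.zeros(n)
        src_t = np.clip(t - coupling.lag - warp, 0.0, None)
        src_axis = np.arange(len(demo_drift)) / sample_rate
        shifted = np.interp(src_t, src_axis, demo_drift)
        drift = kappa * shifted + math.sqrt(1.0 - kappa ** 2) * own
    else:
        drift = own
    return SignalTrace(values + drift, fs=sample_rate, role="observer",
                       block=schedule.block, phase=phase)


# ---------------------------------------------------------------------------
# Whole-experiment datasets
# ---------------------------------------------------------------------------

@dataclass
class BlockRecord:
    """One block of one dyad: schedule plus four traces."""

    block: int
    schedule: EventSchedule
    traces: dict[tuple[str, str], SignalTrace]  # (role, phase) -> trace

    def trace(self, role: str, phase: str) -> SignalTrace:
        return self.traces[(role, phase)]


@dataclass
class DyadRecord:
    dyad_id: str
    kappa: float
    blocks: list[BlockRecord]


@dataclass
class DyadDataset:
    """A full synthetic experiment with its generative ground truth."""

    design: DesignConfig
    coupling: CouplingConfig
    dyads: list[DyadRecord]
    seed: int

    def __iter__(self):
        return iter(self.dyads)

    def __len__(self) -> int:
        return len(self.dyads)

    def observer_person(self, block: int) -> str:
        """Which member (A/B) observes in ``block`` (roles reverse mid-way)."""
        return "A" if block <= self.design.n_blocks // 2 else "B"

    def observer_id(self, dyad_id: str, block: int) -> str:
        return f"{dyad_id}-{self.observer_person(block)}"

    def ground_truth(self):
        import pandas as pd

        return pd.DataFrame({"dyad_id": [d.dyad_id for d in self.dyads],
                             "kappa": [d.kappa for d in self.dyads]})


def generate_dataset(
    design: DesignConfig,
    coupling_sampler: Callable[[np.random.Generator], float] | None = None,
    seed: int | None = None,
    coupling: CouplingConfig | None = None,
    kernels: dict[str, SCRKernel] | None = None,
) -> DyadDataset:
    """Generate a complete multi-dyad experiment.

    Parameters
    ----------
    design : DesignConfig
        Trial-structure constants.
    coupling_sampler : callable, optional
        Draws one ``kappa`` per dyad from an rng; defaults to uniform [0, 1].
    seed : int, optional
        Overrides ``design.seed``. All randomness flows through one
        ``numpy.random.Generator`` seeded here; identical seeds give
        identical datasets.
    coupling : CouplingConfig, optional
        Template for all non-kappa coupling parameters.
    kernels : dict, optional
        Per-event-type SCR kernels (see :func:`default_kernels`).
    """
    if design.n_dyads < 2:
        raise ValueError("need at least 2 dyads (pseudo-dyad analyses require it)")
    sampler = coupling_sampler or (lambda rng: float(rng.uniform(0.0, 1.0)))
    template = coupling or CouplingConfig()
    kerns = kernels or default_kernels()
    used_seed = design.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)

    dyads = []
    width = len(str(design.n_dyads))
    for d in range(design.n_dyads):
        dyad_id = f"d{d + 1:0{width}d}"
        kappa = sampler(rng)
        cpl = replace(template, kappa=kappa)
        blocks = []
        for b in range(1, design.n_blocks + 1):
            schedule = make_schedule(design, b, rng)
            traces: dict[tuple[str, str], SignalTrace] = {}
            for phase in ("learning", "testing"):
                demo, demo_events = synth_demonstrator_trace(
                    schedule, kerns, cpl, rng, phase=phase,
                    sample_rate=design.sample_rate)
                obs = synth_observer_trace(
                    demo_events, schedule, cpl, kerns, rng, phase=phase,
                    sample_rate=design.sample_rate,
                    demo_drift=demo.meta.get("drift"))
                for trace in (demo, obs):
                    trace.dyad_id = dyad_id
                traces[("demonstrator", phase)] = demo
                traces[("observer", phase)] = obs
            blocks.append(BlockRecord(block=b, schedule=schedule, traces=traces))
        dyads.append(DyadRecord(dyad_id=dyad_id, kappa=kappa, blocks=blocks))
    return DyadDataset(design=design, coupling=template, dyads=dyads,
                       seed=used_seed)
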