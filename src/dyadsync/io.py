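"""CSV dialects and configuration files.

Long-format signals: ``dyad_id, role, block, phase, time_s, eda_us`` with
1-based blocks and times in seconds from phase start. Events:
``dyad_id, block, phase, trial_index, cs, onset_s, duration_s, shock,
shock_time_s`` (``shock_time_s`` empty when none). Ground truth:
``dyad_id, kappa``. Run configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crqa import CRQAConfig
from .preprocess import PreprocessConfig
from .synthetic import (CouplingConfig, DesignConfig, DyadDataset, DyadRecord,
                        BlockRecord, EventSchedule, Trial)
from .traces import SignalTrace

__all__ = [
    "SIGNAL_COLUMNS", "EVENT_COLUMNS",
    "signals_frame", "events_frame",
    "write_dataset", "read_signals", "read_events", "load_dataset",
    "RunConfig", "write_manifest",
]

SIGNAL_COLUMNS = ["dyad_id", "role", "block", "phase", "time_s", "eda_us"]
EVENT_COLUMNS = ["dyad_id", "block", "phase", "trial_index", "cs", "onset_s",
                 "duration_s", "shock", "shock_time_s"]


def signals_frame(dataset: DyadDataset) -> pd.DataFrame:
    parts = []
    for dyad in dataset:
        for rec in dyad.blocks:
            for (role, phase), tr in rec.traces.items():
                parts.append(pd.DataFrame({
                    "dyad_id": dyad.dyad_id, "role": role, "block": rec.block,
                    "phase": phase, "time_s": tr.times,
                    "eda_us": tr.values}))
    return pd.concat(parts, ignore_index=True)


def events_frame(dataset: DyadDataset) -> pd.DataFrame:
    rows = []
    for dyad in dataset:
        for rec in dyad.blocks:
            for t in rec.schedule.trials:
                rows.append({
                    "dyad_id": dyad.dyad_id, "block": rec.block,
                    "phase": t.phase, "trial_index": t.index, "cs": t.cs,
                    "onset_s": t.onset, "duration_s": t.duration,
                    "shock": int(t.shock),
                    "shock_time_s": t.shock_time if t.shock else np.nan})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_dataset(dataset: DyadDataset, out_dir: str | Path,
                  float_fmt: str = "%.6f") -> dict[str, Path]:
    """Write signals, events and ground truth CSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"signals": out / "signals.csv", "events": out / "events.csv",
             "ground_truth": out / "ground_truth.csv"}
    signals_frame(dataset).to_csv(paths["signals"], index=False,
                                  float_format=float_fmt)
    events_frame(dataset).to_csv(paths["events"], index=False,
                                 float_format=float_fmt)
    dataset.ground_truth().to_csv(paths["ground_truth"], index=False)
    return paths


def _rows(idx) -> str:
    """1-based data row numbers (header excluded) for error messages."""
    return ", ".join(str(i + 2) for i in list(idx)[:5])


def read_signals(path: str | Path) -> dict[tuple, SignalTrace]:
    """Read a long-format signals CSV into traces keyed
    ``(dyad_id, role, block, phase)``.

    Rows may arrive in any order; the reader sorts within each trace.
    Duplicated time stamps and non-uniform sampling (jitter beyond half a
    sample period, e.g. gaps) are rejected with row numbers.
    """
    df = pd.read_csv(path)
    missing = set(SIGNAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"signals file {path} missing columns {sorted(missing)}")
    traces: dict[tuple, SignalTrace] = {}
    for key, g in df.groupby(["dyad_id", "role", "block", "phase"], sort=True):
        g = g.sort_values("time_s", kind="mergesort")
        t = g["time_s"].to_numpy(dtype=float)
        dup = g.index[pd.Series(t).duplicated().to_numpy()]
        if len(dup):
            raise ValueError(
                f"duplicated (dyad,role,block,phase,time) at rows {_rows(dup)}")
        if len(t) < 2:
            raise ValueError(f"trace {key} has fewer than 2 samples")
        dt = np.diff(t)
        period = np.median(dt)
        bad = np.abs(dt - period) > 0.5 * period
        if bad.any():
            raise ValueError(
                f"non-uniform sampling in trace {key} near rows "
                f"{_rows(g.index[1:][bad])}")
        key = (key[0], key[1], int(key[2]), key[3])
        traces[key] = SignalTrace(g["eda_us"].to_numpy(dtype=float),
                                  fs=1.0 / period, dyad_id=key[0],
                                  role=key[1], block=key[2], phase=key[3],
                                  t0=float(t[0]))
    return traces


def read_events(path: str | Path) -> dict[tuple, EventSchedule]:
    """Read an events CSV into schedules keyed ``(dyad_id, block)``."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns {sorted(missing)}")
    schedules: dict[tuple, EventSchedule] = {}
    for (dyad, block), g in df.groupby(["dyad_id", "block"], sort=True):
        trials = []
        for _, r in g.sort_values(["phase", "trial_index"]).iterrows():
            shock = bool(int(r["shock"]))
            trials.append(Trial(
                phase=str(r["phase"]), index=int(r["trial_index"]),
                cs=str(r["cs"]), onset=float(r["onset_s"]),
                duration=float(r["duration_s"]), shock=shock,
                shock_time=float(r["shock_time_s"]) if shock else None))
        order = {"learning": 0, "testing": 1}
        trials.sort(key=lambda t: (order.get(t.phase, 2), t.index))
        schedules[(dyad, int(block))] = EventSchedule(block=int(block),
                                                      trials=trials)
    return schedules


def load_dataset(signals_path: str | Path, events_path: str | Path,
                 ground_truth_path: str | Path | None = None) -> DyadDataset:
    """Reassemble a :class:`DyadDataset` from its CSV files.

    Design constants are inferred from the data where possible; the
    coupling config is the default template (ground-truth kappa, if a file
    is given, is attached per dyad and round-trips exactly).
    """
    traces = read_signals(signals_path)
    schedules = read_events(events_path)
    kappa = {}
    if ground_truth_path is not None:
        gt = pd.read_csv(ground_truth_path)
        kappa = dict(zip(gt["dyad_id"].astype(str), gt["kappa"].astype(float)))

    dyad_ids = sorted({k[0] for k in traces})
    blocks_per = sorted({k[1] for k in schedules})
    some = next(iter(traces.values()))
    a_sched = next(iter(schedules.values()))
    n_learn = len(a_sched.learning_trials) // 2
    design = DesignConfig(
        n_dyads=len(dyad_ids), n_blocks=len(blocks_per),
        n_cs_each_learning=n_learn,
        n_shocked_csplus=sum(t.shock for t in a_sched.learning_trials),
        cs_duration=a_sched.trials[0].duration,
        n_cs_each_testing=len(a_sched.testing_trials) // 2,
        sample_rate=some.fs)
    dyads = []
    for d in dyad_ids:
        recs = []
        for b in blocks_per:
            if (d, b) not in schedules:
                raise ValueError(f"no events for dyad {d} block {b}")
            tr = {}
            for role in ("demonstrator", "observer"):
                for phase in ("learning", "testing"):
                    if (d, role, b, phase) not in traces:
                        raise ValueError(
                            f"missing trace dyad={d} role={role} block={b} "
                            f"phase={phase}")
                    tr[(role, phase)] = traces[(d, role, b, phase)]
            recs.append(BlockRecord(block=b, schedule=schedules[(d, b)],
                                    traces=tr))
        dyads.append(DyadRecord(dyad_id=d, kappa=kappa.get(d, float("nan")),
                                blocks=recs))
    return DyadDataset(design=design, coupling=CouplingConfig(), dyads=dyads,
                       seed=-1)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (CLI ``run-all``)."""

    out_dir: str = "dyadsync_out"
    signals: str | None = None
    events: str | None = None
    ground_truth: str | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    crqa: CRQAConfig = field(default_factory=CRQAConfig)
    n_permutations: int = 0
    backend: str = "mixedlm"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, typ in (("design", DesignConfig),
                         ("coupling", CouplingConfig),
                         ("preprocess", PreprocessConfig),
                         ("crqa", CRQAConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                for tup in ("iti_range", "scr_window", "baseline_window",
                            "target_band"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = typ(**sub)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_manifest(out_dir: str | Path, stage: str, seed: int | None,
                   config: dict, extra: dict | None = None) -> Path:
    """Record seed, config and package version next to a stage's outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "seed": seed, "version": __version__,
               "config": config}
    payload.update(extra or {})
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
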