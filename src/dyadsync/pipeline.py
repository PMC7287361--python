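"""Stage orchestration: dataset → CRQA metrics → synchrony scores → models.

Each stage is a thin, testable function over plain containers; `run_full`
chains them the way the CLI's ``run-all`` does. The prepared-input step
fixes the analysis frame used everywhere:

* CRQA operates on each dyad-block's *learning-phase* demonstrator and
  observer traces, downsampled to 8 Hz and z-scored (optionally cropped to
  a fixed length first, for reduced-cost simulation studies);
* the regression response is the observer's *testing-phase* trial table;
* alternative predictors (UCS response, learning-phase CS differentiation,
  lagged correlation) come from the observer's learning phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crqa import CRQAConfig, RadiusCalibrationError, run_crqa
from .inference import (FitResult, ModelSpec, PermutationResult, fit_cs_model,
                        fit_specificity_model, pseudo_dyad_null,
                        stability_model)
from .preprocess import (PreprocessConfig, downsample, score_phase,
                         ucs_responses, zscore)
from .synchrony import PCAReport, lagged_correlation, learning_csdiff, \
    pca_synchrony
from .synthetic import DyadDataset

__all__ = [
    "PreparedData",
    "AnalysisResult",
    "prepare_inputs",
    "crqa_table",
    "synchrony_scores",
    "attach_scores",
    "run_full",
]

ALT_PREDICTORS = ["ucs_mean", "learn_csdiff", "lagged_r"]


@dataclass
class PreparedData:
    """Analysis-ready views of one dataset."""

    pairs: list[tuple]              # (dyad_id, block, demo_vals, obs_vals)
    trials: pd.DataFrame            # observer testing-phase trial responses
    learning_trials: pd.DataFrame   # observer learning-phase trial responses
    alt: pd.DataFrame               # per dyad-block alternative predictors


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame
    failures: list[dict]
    scores: pd.DataFrame
    pca_report: PCAReport
    trials: pd.DataFrame
    fits: dict[str, FitResult] = field(default_factory=dict)
    permutation: PermutationResult | None = None


def _crqa_ready_values(trace, cfg: PreprocessConfig, crop_s: float | None):
    ds = downsample(trace, cfg.target_hz)
    if crop_s is not None:
        ds = ds.crop(crop_s)
    return zscore(ds).values


def prepare_inputs(dataset: DyadDataset, cfg: PreprocessConfig | None = None,
                   crqa_crop_s: float | None = None,
                   compute_alt: bool = True) -> PreparedData:
    """Preprocess every dyad-block of a dataset into analysis inputs.

    ``crqa_crop_s`` truncates the 8 Hz learning-phase series to a fixed
    length before z-scoring — used by reduced-cost simulation studies; trial
    scoring always uses the full raw traces. ``compute_alt=False`` skips the
    alternative predictors (and the learning-phase trial scoring they need)
    when only the synchrony analysis is required.
    """
    cfg = cfg or PreprocessConfig()
    pairs, test_rows, learn_rows, alt_rows = [], [], [], []
    for dyad in dataset:
        for rec in dyad.blocks:
            demo_l = rec.trace("demonstrator", "learning")
            obs_l = rec.trace("observer", "learning")
            obs_t = rec.trace("observer", "testing")
            pairs.append((dyad.dyad_id, rec.block,
                          _crqa_ready_values(demo_l, cfg, crqa_crop_s),
                          _crqa_ready_values(obs_l, cfg, crqa_crop_s)))

            observer_id = dataset.observer_id(dyad.dyad_id, rec.block)
            person = dataset.observer_person(rec.block)
            blocks_of = [b.block for b in dyad.blocks
                         if dataset.observer_person(b.block) == person]
            meta = {
                "observer_id": observer_id,
                "role_first": person == "A",
                "block_in_role": blocks_of.index(rec.block) + 1,
                "kappa": dyad.kappa,
            }
            tt = score_phase(obs_t, rec.schedule, cfg, phase="testing")
            test_rows.append(tt.assign(**meta))
            if not compute_alt:
                continue
            lt = score_phase(obs_l, rec.schedule, cfg, phase="learning")
            learn_rows.append(lt.assign(**meta))

            _, ucs_mean = ucs_responses(obs_l, rec.schedule, cfg)
            r, lag = lagged_correlation(
                zscore(downsample(demo_l, cfg.target_hz)),
                zscore(downsample(obs_l, cfg.target_hz)))
            alt_rows.append({
                "dyad_id": dyad.dyad_id, "block": rec.block,
                "ucs_mean": float(cfg.apply_transform(ucs_mean)),
                "learn_csdiff": learning_csdiff(lt),
                "lagged_r": r, "lagged_lag_s": lag,
            })
    return PreparedData(
        pairs=pairs,
        trials=pd.concat(test_rows, ignore_index=True),
        learning_trials=(pd.concat(learn_rows, ignore_index=True)
                         if learn_rows else pd.DataFrame()),
        alt=pd.DataFrame(alt_rows),
    )


def crqa_table(prepared: PreparedData,
               cfg: CRQAConfig | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Per dyad-block CRQA metrics; calibration failures are collected,
    not raised, so they can be logged and excluded downstream."""
    cfg = cfg or CRQAConfig()
    rows, failures = [], []
    for dyad_id, block, demo, obs in prepared.pairs:
        try:
            m = run_crqa(demo, obs, cfg)
        except RadiusCalibrationError as err:
            failures.append({"dyad_id": dyad_id, "block": block,
                             "reason": str(err),
                             "achieved_rr": err.achieved_rr})
            continue
        rows.append({"dyad_id": dyad_id, "block": block, **m.as_dict()})
    return pd.DataFrame(rows), failures


def synchrony_scores(metrics: pd.DataFrame,
                     alt: pd.DataFrame | None = None) -> tuple[pd.DataFrame, PCAReport]:
    """PCA scores per dyad-block, merged with the alternative predictors."""
    scores, report = pca_synchrony(metrics)
    if alt is not None:
        scores = scores.merge(alt, on=["dyad_id", "block"], how="left")
    return scores, report


def attach_scores(trials: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Merge per dyad-block scores onto the trial table (inner join: trials
    from dyad-blocks that failed CRQA calibration drop out here)."""
    return trials.merge(scores, on=["dyad_id", "block"], how="inner")


def run_full(dataset: DyadDataset,
             pre_cfg: PreprocessConfig | None = None,
             crqa_cfg: CRQAConfig | None = None,
             spec: ModelSpec | None = None,
             n_permutations: int = 0,
             seed: int | None = None,
             crqa_crop_s: float | None = None,
             with_stability: bool = True) -> AnalysisResult:
    """The complete analysis chain on one dataset.

    Stages: preprocessing → per dyad-block CRQA → PCA synchrony component +
    alternative predictors → multilevel CS model, specificity model and
    (optionally) stability model → optional pseudo-dyad permutation test.
    """
    prepared = prepare_inputs(dataset, pre_cfg, crqa_crop_s)
    metrics, failures = crqa_table(prepared, crqa_cfg)
    scores, report = synchrony_scores(metrics, prepared.alt)
    trials = attach_scores(prepared.trials, scores)

    fits = {"cs": fit_cs_model(trials, predictors=("pc1",), spec=spec, seed=seed),
            "specificity": fit_specificity_model(trials, spec=spec, seed=seed)}
    if with_stability and trials["block_in_role"].nunique() == 2:
        fits["stability"] = stability_model(
            trials, block_col="block_in_role", spec=spec, seed=seed)

    permutation = None
    if n_permutations > 0:
        permutation = pseudo_dyad_null(
            prepared.pairs, prepared.trials, n_permutations=n_permutations,
            seed=seed, crqa_cfg=crqa_cfg, spec=spec)
    return AnalysisResult(metrics=metrics, failures=failures, scores=scores,
                          pca_report=report, trials=trials, fits=fits,
                          permutation=permutation)
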