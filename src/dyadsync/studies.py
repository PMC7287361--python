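"""Preset simulation studies: calibration, recovery, power and specificity.

These functions encode the package's standard validation experiments at
fixed, documented problem sizes (see docs/methods.md for the rationale
behind each size and scenario). They are consumed by the example scripts
and by the reproduction script; each takes an explicit seed and returns
plain numbers or small frames.

Two named generator scenarios are used besides the defaults:

* ``strong_link`` — a strong-contrast coupling manipulation: half the dyads
  weakly (kappa = 0.1) and half strongly (kappa = 0.9) coupled, with a
  large, non-extinguishing coupling→learning slope. This is the condition
  under which the CS×synchrony interaction should be reliably detectable.
* ``no_link`` — the same design with ``learning_gain = 0``: synchrony varies
  but carries no information about testing-phase CS differentiation.
"""

from __future__ import annotations

import numpy as np

from .crqa import CRQAConfig
from .inference import (FitResult, ModelSpec, PermutationResult, fit_cs_model,
                        pseudo_dyad_null)
from .pipeline import attach_scores, crqa_table, prepare_inputs, \
    synchrony_scores
from .synthetic import CouplingConfig, DesignConfig, generate_dataset

__all__ = [
    "strong_link_coupling",
    "bimodal_kappa",
    "calibration_study",
    "recovery_study",
    "interaction_replicate",
    "specificity_study",
    "null_calibration_study",
]

#: Learning-trace length (s) used by the reduced-cost replicate studies.
REPLICATE_CROP_S = 144.0


def strong_link_coupling(learning_gain: float = 3.5) -> CouplingConfig:
    """Coupling parameters of the strong-link scenario (µS-scale effects)."""
    return CouplingConfig(learning_gain=learning_gain, beta0=1.2,
                          extinction_rate=0.0)


def bimodal_kappa(rng: np.random.Generator) -> float:
    """Strong-contrast coupling sampler: kappa 0.1 or 0.9, equiprobable."""
    return 0.1 if rng.random() < 0.5 else 0.9


def calibration_study(n_dyads: int = 20, seed: int = 0,
                      crqa_cfg: CRQAConfig | None = None) -> dict:
    """Mean achieved recurrence rate after full per-dyad parameter selection.

    Simulates ``n_dyads`` dyads at the default 32 Hz, downsamples the
    learning-phase signals to 8 Hz, z-scores them, runs delay/dimension/
    radius selection per dyad and averages the achieved recurrence rates.
    """
    design = DesignConfig(n_dyads=n_dyads, n_blocks=1, seed=seed)
    ds = generate_dataset(design, seed=seed)
    prep = prepare_inputs(ds, compute_alt=False)
    metrics, failures = crqa_table(prep, crqa_cfg)
    return {
        "mean_rr": float(metrics["rr"].mean()),
        "min_rr": float(metrics["rr"].min()),
        "max_rr": float(metrics["rr"].max()),
        "n_dyads": len(metrics),
        "n_failures": len(failures),
    }


def recovery_study(n_dyads: int = 69, n_blocks: int = 4, seed: int = 0,
                   crop_s: float = 160.0) -> dict:
    """Correlation between per-dyad mean synchrony (PC1) and true kappa.

    Uses the default generator (uniform kappa, moderate coupling→learning
    link) at the full block design; PC1 is averaged over each dyad's blocks
    before correlating with the generative kappa.
    """
    design = DesignConfig(n_dyads=n_dyads, n_blocks=n_blocks, sample_rate=8,
                          seed=seed)
    ds = generate_dataset(design, seed=seed)
    prep = prepare_inputs(ds, crqa_crop_s=crop_s, compute_alt=False)
    metrics, _ = crqa_table(prep)
    scores, report = synchrony_scores(metrics)
    per_dyad = scores.groupby("dyad_id")["pc1"].mean().reset_index()
    merged = ds.ground_truth().merge(per_dyad, on="dyad_id")
    r = float(np.corrcoef(merged["kappa"], merged["pc1"])[0, 1])
    return {"r_pc1_kappa": r, "pc1_variance_share": report.pc1_share,
            "n_dyads": len(merged)}


def interaction_replicate(seed: int, learning_gain: float = 3.5,
                          n_dyads: int = 69, n_blocks: int = 2,
                          crop_s: float = REPLICATE_CROP_S,
                          spec: ModelSpec | None = None) -> FitResult:
    """One replicate of the CS×synchrony interaction study.

    Generates a strong-contrast dataset (``learning_gain = 0`` for null
    replicates), runs CRQA → PCA → the trial-level multilevel model, and
    returns the fit (the ``cs_code:pc1`` term is the quantity of interest).
    """
    design = DesignConfig(n_dyads=n_dyads, n_blocks=n_blocks, sample_rate=8,
                          seed=seed)
    ds = generate_dataset(design, coupling_sampler=bimodal_kappa, seed=seed,
                          coupling=strong_link_coupling(learning_gain))
    prep = prepare_inputs(ds, crqa_crop_s=crop_s, compute_alt=False)
    metrics, _ = crqa_table(prep)
    scores, _ = synchrony_scores(metrics)
    trials = attach_scores(prep.trials, scores)
    return fit_cs_model(trials, predictors=("pc1",), spec=spec, seed=seed)


def specificity_study(n_dyads: int = 32, n_blocks: int = 2, seed: int = 0,
                      n_permutations: int = 200,
                      crop_s: float = REPLICATE_CROP_S) -> PermutationResult:
    """Pseudo-dyad permutation test under active coupling."""
    design = DesignConfig(n_dyads=n_dyads, n_blocks=n_blocks, sample_rate=8,
                          seed=seed)
    ds = generate_dataset(design, coupling_sampler=bimodal_kappa, seed=seed,
                          coupling=strong_link_coupling())
    prep = prepare_inputs(ds, crqa_crop_s=crop_s, compute_alt=False)
    return pseudo_dyad_null(prep.pairs, prep.trials,
                            n_permutations=n_permutations, seed=seed + 1)


def null_calibration_study(n_meta: int = 20, n_dyads: int = 8,
                           n_permutations: int = 100, seed: int = 0,
                           crop_s: float = 48.0) -> list[float]:
    """Permutation p-values under kappa ≡ 0 (no true pairing structure).

    Under exchangeability of pairings the p-values should be uniform-like;
    the single-level (OLS) backend is used inside the permutations since
    calibration is a property of the permutation scheme, not of the model.
    """
    ps = []
    for m in range(n_meta):
        s = seed + 101 * m
        design = DesignConfig(n_dyads=n_dyads, n_blocks=1, sample_rate=8,
                              seed=s)
        ds = generate_dataset(design, coupling_sampler=lambda rng: 0.0,
                              seed=s)
        prep = prepare_inputs(ds, crqa_crop_s=crop_s, compute_alt=False)
        res = pseudo_dyad_null(prep.pairs, prep.trials,
                               n_permutations=n_permutations, seed=s + 1,
                               spec=ModelSpec(backend="ols"))
        ps.append(res.p_value)
    return ps
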