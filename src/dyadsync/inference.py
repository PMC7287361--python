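"""Trial-level regression models and the pseudo-dyad permutation null.

The central question — does learning-phase physiological synchrony predict
the observer's later CS differentiation? — is answered by a trial-level
multilevel regression of testing-phase SCR amplitudes on deviation-coded CS
status (±0.5), standardised continuous predictors, and their interactions,
with varying intercepts and CS slopes (and their correlation) by observer.
The default backend is restricted maximum likelihood (statsmodels MixedLM)
reporting point estimates, standard errors and Wald 95% intervals; a
single-level OLS backend is available for degenerate designs and checks.

Specificity is probed with a permutation test over *pseudo-dyads*: each
observer is re-paired with a demonstrator from a different dyad (a
derangement over dyad ids, block structure preserved), the entire
CRQA → PCA → regression pipeline is re-run per pairing, and the observed
CS×synchrony interaction is compared against the null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import crqa as _crqa
from .synchrony import pca_synchrony

__all__ = [
    "ModelSpec",
    "FitResult",
    "PermutationResult",
    "ModelFitError",
    "standardize",
    "deviation_code",
    "fit_cs_model",
    "fit_specificity_model",
    "stability_model",
    "derangement",
    "pseudo_dyad_null",
]


class ModelFitError(RuntimeError):
    """Model could not be estimated; message carries diagnostics."""


def standardize(x: pd.Series | np.ndarray, name: str = "predictor") -> np.ndarray:
    """Center and scale to SD 1; zero variance is an error, not a NaN."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"cannot standardize zero-variance column {name!r}")
    return (arr - arr.mean()) / sd


def deviation_code(x: pd.Series | np.ndarray, name: str = "factor") -> np.ndarray:
    """Map a two-level factor onto {−0.5, +0.5} (sorted order)."""
    arr = np.asarray(x)
    levels = np.unique(arr)
    if len(levels) != 2:
        raise ValueError(
            f"cannot deviation-code column {name!r} with {len(levels)} "
            f"level(s); need exactly 2")
    return np.where(arr == levels[1], 0.5, -0.5)


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and how."""

    response: str = "amplitude_tx"
    cs_col: str = "cs_code"
    group_col: str = "observer_id"
    backend: str = "mixedlm"       # "mixedlm" (REML) | "ols" (single level)

    def __post_init__(self) -> None:
        if self.backend not in ("mixedlm", "ols"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class FitResult:
    """Fixed-effect estimates with Wald 95% intervals, plus diagnostics."""

    terms: pd.DataFrame            # index: term; estimate, se, ci_lo, ci_hi
    random_effects: dict
    backend: str
    formula: str
    n_obs: int
    n_groups: int
    converged: bool
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        if name not in self.terms.index:
            raise KeyError(f"no term {name!r}; have {list(self.terms.index)}")
        return self.terms.loc[name]

    def estimate(self, name: str) -> float:
        return float(self.term(name)["estimate"])

    def ci_excludes_zero(self, name: str) -> bool:
        t = self.term(name)
        return bool(t["ci_lo"] > 0 or t["ci_hi"] < 0)


def _check_trials(df: pd.DataFrame, spec: ModelSpec,
                  predictors: tuple[str, ...]) -> pd.DataFrame:
    need = {spec.response, spec.cs_col, spec.group_col, *predictors}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    cs = df[spec.cs_col].to_numpy(dtype=float)
    if not np.all(np.isin(np.round(cs, 12), [0.5, -0.5])):
        raise ValueError(f"{spec.cs_col} must be deviation coded ±0.5")
    levels = df.groupby(spec.group_col)[spec.cs_col].nunique()
    bad = levels[levels < 2]
    if not bad.empty:
        raise ValueError(
            f"observers missing a CS level: {list(bad.index)[:5]}")
    out = df.copy()
    for p in predictors:
        out[p] = standardize(out[p], name=p)
    return out


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate aliased pairs for the error message
        c = np.corrcoef(X, rowvar=False)
        aliased = [(names[i], names[j])
                   for i in range(len(names)) for j in range(i + 1, len(names))
                   if abs(c[i, j]) > 1 - 1e-10]
        raise ModelFitError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {aliased or 'not pairwise identifiable'}")


def _fit(df: pd.DataFrame, formula: str, spec: ModelSpec,
         seed: int | None) -> FitResult:
    y_sd = df[spec.response].std()
    backend = spec.backend
    if backend == "mixedlm" and (y_sd == 0 or df[spec.group_col].nunique() < 2):
        backend = "ols"     # degenerate response/grouping: single level exact

    if backend == "mixedlm":
        model = smf.mixedlm(formula, data=df, groups=df[spec.group_col],
                            re_formula=f"~{spec.cs_col}")
        _check_rank(model.exog, list(model.exog_names))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        fe = res.fe_params
        if not np.all(np.isfinite(fe)):
            raise ModelFitError(f"non-finite fixed effects: {dict(fe)}")
        se = res.bse_fe
        ci = res.conf_int().loc[fe.index]
        cov_re = np.asarray(res.cov_re)
        sd_i = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        sd_s = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        corr = float(cov_re[0, 1] / (sd_i * sd_s)) if sd_i > 0 and sd_s > 0 else np.nan
        ranef = {"sd_intercept": sd_i, "sd_cs_slope": sd_s,
                 "corr_intercept_slope": corr,
                 "sd_residual": float(np.sqrt(res.scale))}
        converged = bool(getattr(res, "converged", True))
    else:
        model = smf.ols(formula, data=df)
        _check_rank(model.exog, list(model.exog_names))
        res = model.fit()
        fe, se, ci = res.params, res.bse, res.conf_int()
        ranef = {"sd_residual": float(np.sqrt(res.scale))}
        converged = True

    terms = pd.DataFrame({
        "estimate": fe,
        "se": se,
        "ci_lo": ci.iloc[:, 0],
        "ci_hi": ci.iloc[:, 1],
    })
    return FitResult(terms=terms, random_effects=ranef, backend=backend,
                     formula=formula, n_obs=len(df),
                     n_groups=int(df[spec.group_col].nunique()),
                     converged=converged, seed=seed)


def fit_cs_model(trials: pd.DataFrame, predictors: tuple[str, ...] = ("pc1",),
                 spec: ModelSpec | None = None,
                 seed: int | None = None) -> FitResult:
    """Regress testing-phase responses on CS status and synchrony predictors.

    Fits ``response ~ cs * (p1 + p2 + ...)`` with varying intercepts and CS
    slopes by observer. Callers should supply ≥ 10 observers with both CS
    levels each; predictors are standardised at fit time, the CS column must
    be deviation coded ±0.5.
    """
    spec = spec or ModelSpec()
    df = _check_trials(trials, spec, tuple(predictors))
    rhs = spec.cs_col
    if predictors:
        rhs = f"{spec.cs_col} * ({' + '.join(predictors)})"
    formula = f"{spec.response} ~ {rhs}"
    return _fit(df, formula, spec, seed)


def fit_specificity_model(trials: pd.DataFrame,
                          predictors: tuple[str, ...] = (
                              "pc1", "ucs_mean", "learn_csdiff", "lagged_r"),
                          spec: ModelSpec | None = None,
                          seed: int | None = None) -> FitResult:
    """Joint model of the synchrony component and the three alternatives.

    All four predictors enter together with their CS interactions, so the
    CS×synchrony term is adjusted for every rival account.
    """
    if len(predictors) < 2:
        raise ValueError("specificity model needs at least two predictors")
    return fit_cs_model(trials, predictors=tuple(predictors), spec=spec,
                        seed=seed)


def stability_model(trials: pd.DataFrame, pc_col: str = "pc1",
                    block_col: str = "block", role_col: str = "role_first",
                    trial_col: str = "trial_index",
                    spec: ModelSpec | None = None,
                    seed: int | None = None) -> FitResult:
    """Does the synchrony effect vary by block, starting role, or trial?

    Adds CS×Block, CS×Role and the CS×synchrony×trial interaction to the
    base model. Block and role are deviation coded ±0.5; the trial index is
    standardised.
    """
    spec = spec or ModelSpec()
    df = trials.copy()
    df["block_code"] = deviation_code(df[block_col], name=block_col)
    df["role_code"] = deviation_code(df[role_col], name=role_col)
    df["trial_z"] = standardize(df[trial_col], name=trial_col)
    df = _check_trials(df, spec, (pc_col,))
    formula = (f"{spec.response} ~ {spec.cs_col} * {pc_col} * trial_z "
               f"+ {spec.cs_col} * block_code + {spec.cs_col} * role_code")
    return _fit(df, formula, spec, seed)


# ---------------------------------------------------------------------------
# Pseudo-dyad permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed interaction vs. its pseudo-dyad null distribution."""

    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int
    term: str
    n_failed: int = 0

    def summary(self) -> dict:
        return {"observed": self.observed, "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "null_mean": float(np.mean(self.null)) if len(self.null) else np.nan,
                "null_q95": float(np.quantile(self.null, 0.95)) if len(self.null) else np.nan,
                "term": self.term, "n_failed": self.n_failed}


def derangement(rng: np.random.Generator, n: int, max_tries: int = 10000) -> np.ndarray:
    """A uniformly random permutation of ``range(n)`` with no fixed point."""
    if n < 2:
        raise ValueError("no derangement exists for fewer than 2 items")
    for _ in range(max_tries):
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p
    raise RuntimeError("failed to draw a derangement")  # pragma: no cover


class _DimCache:
    """Memoises per-signal FNN dimension choices across pairings.

    Delay and dimension selection are deterministic per signal (and per
    delay), so re-pairing signals never changes the per-signal answers;
    only the radius calibration is pair-specific and is redone from scratch
    for every pseudo-pairing.
    """

    def __init__(self, cfg: _crqa.CRQAConfig):
        self.cfg = cfg
        self._dims: dict[tuple, int] = {}

    def dim(self, key: tuple, series: np.ndarray, delay: int) -> int:
        k = (*key, delay)
        if k not in self._dims:
            self._dims[k] = _crqa.select_dim(
                series, delay, max_dim=self.cfg.max_dim, rtol=self.cfg.rtol,
                threshold=self.cfg.fnn_threshold)
        return self._dims[k]


def _paired_metrics(pairs: list[tuple], mapping: dict[str, str],
                    delays: dict[tuple, int], cache: _DimCache,
                    cfg: _crqa.CRQAConfig) -> pd.DataFrame:
    """CRQA metrics for every observer dyad-block under a demo re-pairing."""
    demo_map = {(d, b): x for d, b, x, _ in pairs}
    rows = []
    for dyad, block, _, obs in pairs:
        src = mapping[dyad]
        demo = demo_map.get((src, block))
        if demo is None:
            continue
        n = min(len(demo), len(obs))
        x, y = demo[:n], obs[:n]
        delay = max(delays[("demo", src, block)], delays[("obs", dyad, block)])
        dim = max(cache.dim(("demo", src, block), x, delay),
                  cache.dim(("obs", dyad, block), y, delay))
        X, Y = _crqa.embed(x, delay, dim), _crqa.embed(y, delay, dim)
        try:
            radius, _ = _crqa.calibrate_radius(X, Y, cfg.target_band, cfg.norm)
        except _crqa.RadiusCalibrationError:
            continue
        R = _crqa.cross_recurrence(X, Y, radius, cfg.norm)
        m = _crqa.compute_metrics(R, lmin=cfg.lmin, vmin=cfg.vmin)
        rows.append({"dyad_id": dyad, "block": block, **m.as_dict()})
    return pd.DataFrame(rows)


def pseudo_dyad_null(pairs: list[tuple], trials: pd.DataFrame,
                     n_permutations: int = 1000, seed: int | None = None,
                     crqa_cfg: _crqa.CRQAConfig | None = None,
                     spec: ModelSpec | None = None,
                     term: str = "cs_code:pc1") -> PermutationResult:
    """Permutation test of synchrony specificity over pseudo-dyads.

    Parameters
    ----------
    pairs : list of (dyad_id, block, demo_values, obs_values)
        CRQA-ready (downsampled, z-scored) learning-phase signal pairs.
    trials : DataFrame
        Observer testing-phase trial table (``fit_cs_model`` columns minus
        the synchrony score, which is recomputed per pairing).
    n_permutations : int
        Number of derangements over dyad ids (block structure preserved; an
        observer is never re-paired with their own demonstrator).

    For the observed pairing and each pseudo-pairing the full
    CRQA → PCA → multilevel-regression pipeline is re-run and the requested
    interaction coefficient recorded. ``p = (1 + #{null ≥ observed}) /
    (n_valid + 1)``.
    """
    cfg = crqa_cfg or _crqa.CRQAConfig()
    spec = spec or ModelSpec()
    rng = np.random.default_rng(seed)
    dyads = sorted({d for d, *_ in pairs})
    if len(dyads) < 2:
        raise ValueError("pseudo-dyad null needs at least 2 dyads")

    delays: dict[tuple, int] = {}
    for dyad, block, demo, obs in pairs:
        n = min(len(demo), len(obs))
        max_lag = min(cfg.max_lag, n // 4)
        delays[("demo", dyad, block)] = _crqa.select_delay(demo[:n], max_lag)
        delays[("obs", dyad, block)] = _crqa.select_delay(obs[:n], max_lag)
    cache = _DimCache(cfg)

    def interaction(mapping: dict[str, str]) -> float:
        metrics = _paired_metrics(pairs, mapping, delays, cache, cfg)
        if len(metrics) < 5:
            raise ModelFitError("too few calibrated dyad-blocks for PCA")
        scores, _ = pca_synchrony(metrics)
        merged = trials.merge(scores[["dyad_id", "block", "pc1"]],
                              on=["dyad_id", "block"], how="inner")
        fit = fit_cs_model(merged, predictors=("pc1",), spec=spec)
        return fit.estimate(term)

    observed = interaction({d: d for d in dyads})
    null, n_failed = [], 0
    for _ in range(n_permutations):
        p = derangement(rng, len(dyads))
        mapping = {dyads[i]: dyads[p[i]] for i in range(len(dyads))}
        try:
            null.append(interaction(mapping))
        except (ModelFitError, np.linalg.LinAlgError):
            n_failed += 1
    null = np.asarray(null)
    p_value = (1 + int(np.sum(null >= observed))) / (len(null) + 1)
    return PermutationResult(observed=observed, null=null, p_value=p_value,
                             n_permutations=n_permutations, term=term,
                             n_failed=n_failed)
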