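"""Synchrony summarisation: PCA over CRQA metrics and alternative predictors.

The four CRQA metrics (DET, LAM, maxL, rENTR) are strongly correlated, so
they are reduced to a single synchrony component: the first principal
component of their correlation matrix, pooled over all dyad-blocks, with the
sign fixed so it loads positively on the metrics. Three non-synchrony
predictors used in the specificity analysis are also computed here: the
observer's mean response to the social UCS, the observer's learning-phase CS
differentiation, and the maximal time-lagged linear correlation between the
two signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .traces import SignalTrace

__all__ = [
    "METRIC_COLUMNS",
    "PCAReport",
    "pca_synchrony",
    "lagged_correlation",
    "learning_csdiff",
]

#: The CRQA metrics entering the synchrony component, in loading order.
METRIC_COLUMNS = ["det", "lam", "maxl", "rentr"]


@dataclass
class PCAReport:
    """Loadings and variance decomposition of the synchrony PCA."""

    loadings: pd.DataFrame          # components x metrics, unit rows
    variance_explained: np.ndarray  # one proportion per component

    @property
    def pc1_share(self) -> float:
        return float(self.variance_explained[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.loadings.copy()
        out.insert(0, "variance_explained", self.variance_explained)
        return out


def pca_synchrony(metrics: pd.DataFrame,
                  columns: list[str] | None = None) -> tuple[pd.DataFrame, PCAReport]:
    """Reduce the CRQA metrics to principal-component synchrony scores.

    The metric columns are standardised (so the PCA acts on their
    correlation matrix), decomposed, and the first component's sign is
    fixed so its loadings sum positive. Scores are returned standardised,
    one row per input row with identity columns carried through.

    Returns the score table (``pc1`` .. ``pc{k}``) and a :class:`PCAReport`.
    """
    columns = columns or METRIC_COLUMNS
    missing = [c for c in columns if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns {missing}")
    if len(metrics) < 5:
        raise ValueError(f"need at least 5 dyad-block rows, got {len(metrics)}")
    X = metrics[columns].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("metrics table contains non-finite values")
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"metric column {columns[j]!r} is constant; "
                             "cannot enter a correlation-matrix PCA")
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=len(columns))
    scores = pca.fit_transform(Z)
    load = pca.components_.copy()          # rows: components; unit norm
    for k in range(load.shape[0]):
        if load[k].sum() < 0:
            load[k] = -load[k]
            scores[:, k] = -scores[:, k]
    score_sd = scores.std(axis=0)
    score_sd[score_sd == 0] = 1.0
    scores = scores / score_sd

    id_cols = [c for c in ("dyad_id", "block") if c in metrics.columns]
    out = metrics[id_cols].copy() if id_cols else pd.DataFrame(index=metrics.index)
    for k in range(scores.shape[1]):
        out[f"pc{k + 1}"] = scores[:, k]
    report = PCAReport(
        loadings=pd.DataFrame(load, columns=columns,
                              index=[f"pc{k + 1}" for k in range(load.shape[0])]),
        variance_explained=pca.explained_variance_ratio_.copy(),
    )
    return out, report


def lagged_correlation(demo: SignalTrace | np.ndarray,
                       obs: SignalTrace | np.ndarray,
                       fs: float | None = None,
                       max_lag_s: float = 10.0,
                       min_overlap: int = 8) -> tuple[float, float]:
    """Maximal Pearson correlation with the observer shifted later.

    Scans integer-sample lags from 0 to ``max_lag_s`` (observer trailing the
    demonstrator only — the observer reacts to what they see), restricted to
    the overlapping segment, and returns ``(r, lag_seconds)`` at the
    maximising lag.
    """
    if isinstance(demo, SignalTrace):
        fs = fs or demo.fs
        demo = demo.values
    if isinstance(obs, SignalTrace):
        fs = fs or obs.fs
        obs = obs.values
    if fs is None:
        raise ValueError("sampling rate required for array inputs")
    x = np.asarray(demo, float).ravel()
    y = np.asarray(obs, float).ravel()
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    max_k = int(round(max_lag_s * fs))
    if n - max_k < min_overlap:
        raise ValueError(
            f"only {n - max_k} overlapping samples at max lag {max_lag_s}s; "
            f"need at least {min_overlap}")
    best_r, best_lag = -np.inf, 0
    for k in range(max_k + 1):
        a = x[: n - k]
        b = y[k:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_r, best_lag = r, k
    if not np.isfinite(best_r):
        raise ValueError("correlation undefined (constant overlap segments)")
    return best_r, best_lag / fs


def learning_csdiff(trials: pd.DataFrame, value_col: str = "amplitude_tx") -> float:
    """Observer's learning-phase CS differentiation.

    Mean transformed response to CS+ minus CS−; both levels must be present.
    """
    plus = trials.loc[trials["cs_code"] > 0, value_col]
    minus = trials.loc[trials["cs_code"] < 0, value_col]
    if plus.empty or minus.empty:
        raise ValueError("trial table must contain both CS+ and CS− trials")
    return float(plus.mean() - minus.mean())
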