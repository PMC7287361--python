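"""Cross-recurrence quantification analysis (CRQA) from first principles.

Two z-scored signals are lifted into a common phase space by time-delay
embedding; a cross-recurrence matrix marks every pair of time points whose
embedded states fall within a radius of each other; and line structures in
that matrix quantify how the two trajectories co-evolve:

* **RR** — recurrence rate, the density of the matrix;
* **DET** — fraction of recurrent points on diagonal lines (length ≥ 2):
  stretches where the two systems follow parallel paths;
* **LAM** — fraction on vertical lines: one system lingering in a state the
  other visits;
* **maxL** — the longest diagonal line, the strongest uninterrupted episode
  of coupling;
* **rENTR** — normalised Shannon entropy of the diagonal line-length
  distribution, the complexity of the coupling.

Embedding parameters are chosen per signal pair the standard way: the delay
from the first local minimum of average mutual information, the dimension
from false-nearest-neighbour collapse, and the radius calibrated by
bisection so the recurrence rate lands in a 2–4% band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .traces import DegenerateSignalError, SignalTrace

__all__ = [
    "EmbeddingParams",
    "RecurrenceMatrix",
    "CRQAMetrics",
    "CRQAConfig",
    "RadiusCalibrationError",
    "embed",
    "cross_recurrence",
    "diagonal_lines",
    "vertical_lines",
    "compute_metrics",
    "average_mutual_information",
    "select_delay",
    "select_dim",
    "calibrate_radius",
    "run_crqa",
]

_NORMS = {"euclidean": "euclidean", "maximum": "chebyshev"}


class RadiusCalibrationError(RuntimeError):
    """No radius reaches the target recurrence-rate band.

    Carries the closest achievable recurrence rate (``achieved_rr``) and the
    radius that produced it, so callers can log why a dyad-block was dropped.
    """

    def __init__(self, msg: str, achieved_rr: float, radius: float):
        super().__init__(msg)
        self.achieved_rr = achieved_rr
        self.radius = radius


@dataclass(frozen=True)
class EmbeddingParams:
    """Parameters that fix one cross-recurrence plot."""

    delay: int                 # samples
    dim: int                   # embedding dimensions
    radius: float              # neighbourhood size, z-units
    norm: str = "euclidean"    # "euclidean" | "maximum"

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dim < 1:
            raise ValueError("delay and dim must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.norm not in _NORMS:
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass
class RecurrenceMatrix:
    """Binary cross-recurrence matrix; rows index X, columns index Y."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R).astype(bool)
        if self.R.ndim != 2:
            raise ValueError("recurrence matrix must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.R.shape[0]

    @property
    def n_cols(self) -> int:
        return self.R.shape[1]

    @property
    def n_recurrent(self) -> int:
        return int(self.R.sum())


@dataclass
class CRQAMetrics:
    """The four line-based synchrony metrics plus their provenance."""

    rr: float
    det: float
    lam: float
    maxl: int
    rentr: float
    entr: float
    n_recurrent: int
    n_rows: int
    n_cols: int
    params: EmbeddingParams | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"rr": self.rr, "det": self.det, "lam": self.lam,
             "maxl": self.maxl, "rentr": self.rentr, "entr": self.entr,
             "n_recurrent": self.n_recurrent, "n_samples": self.n_rows}
        if self.params is not None:
            d.update(delay=self.params.delay, dim=self.params.dim,
                     radius=self.params.radius, norm=self.params.norm)
        return d


def embed(series: np.ndarray, delay: int, dim: int) -> np.ndarray:
    """Time-delay embedding.

    Vector ``k`` is ``(x[k], x[k+delay], ..., x[k+(dim-1)delay])``; the
    result has ``n - (dim-1)*delay`` rows.
    """
    x = np.asarray(series, dtype=float).ravel()
    if delay < 1 or dim < 1:
        raise ValueError("delay and dim must be >= 1")
    n_vec = len(x) - (dim - 1) * delay
    if n_vec < 1:
        raise ValueError(
            f"series of length {len(x)} too short to embed at dim={dim}, "
            f"delay={delay}; need at least {(dim - 1) * delay + 1} samples")
    return np.column_stack([x[i * delay: i * delay + n_vec] for i in range(dim)])


def cross_recurrence(X_emb: np.ndarray, Y_emb: np.ndarray, radius: float,
                     norm: str = "euclidean") -> RecurrenceMatrix:
    """Threshold the cross-distance matrix at ``radius``.

    ``R[i, j] = 1`` iff ``dist(X_emb[i], Y_emb[j]) <= radius``. No Theiler
    window is applied: the two trajectories belong to different people, so
    near-zero-lag matches are signal, not autocorrelation artifact.
    """
    X_emb, Y_emb = np.atleast_2d(X_emb), np.atleast_2d(Y_emb)
    if X_emb.shape[1] != Y_emb.shape[1]:
        raise ValueError(
            f"embedding dimension mismatch: {X_emb.shape[1]} vs {Y_emb.shape[1]}")
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}")
    D = cdist(X_emb, Y_emb, metric=_NORMS[norm])
    return RecurrenceMatrix(D <= radius)


def _run_lengths(flat: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a separator-delimited 1-D array."""
    x = np.empty(flat.size + 2, dtype=np.int8)
    x[0] = x[-1] = 0
    x[1:-1] = flat
    d = np.diff(x)
    return np.flatnonzero(d == -1) - np.flatnonzero(d == 1)


def _histogram(lengths: np.ndarray, lmin: int) -> dict[int, int]:
    lengths = lengths[lengths >= lmin]
    vals, counts = np.unique(lengths, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def diagonal_lines(R: RecurrenceMatrix | np.ndarray, lmin: int = 1) -> dict[int, int]:
    """Histogram {length: count} of maximal diagonal runs of ones.

    Every diagonal of the (possibly rectangular) matrix is scanned,
    including the main one; runs shorter than ``lmin`` are dropped.
    """
    M = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, dtype=bool)
    n_r, n_c = M.shape
    # Concatenate every diagonal (j - i constant), zero-separated, and scan
    # the result in one run-length pass.
    sep = np.zeros(1, dtype=bool)
    parts = []
    for off in range(-(n_r - 1), n_c):
        parts.append(M.diagonal(off))
        parts.append(sep)
    return _histogram(_run_lengths(np.concatenate(parts)), lmin)


def vertical_lines(R: RecurrenceMatrix | np.ndarray, vmin: int = 1) -> dict[int, int]:
    """Histogram {length: count} of maximal vertical runs of ones."""
    M = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, dtype=bool)
    S = np.vstack([M, np.zeros((1, M.shape[1]), dtype=bool)])
    return _histogram(_run_lengths(S.ravel(order="F")), vmin)


def compute_metrics(R: RecurrenceMatrix | np.ndarray, lmin: int = 2,
                    vmin: int = 2,
                    params: EmbeddingParams | None = None) -> CRQAMetrics:
    """The four CRQA metrics from one recurrence matrix.

    * ``RR = (Σ R) / (n_rows · n_cols)``
    * ``DET = Σ_{l ≥ lmin} l·P(l) / Σ R`` over diagonal runs
    * ``LAM = Σ_{v ≥ vmin} v·P(v) / Σ R`` over vertical runs
    * ``maxL`` = longest diagonal run of any length
    * ``ENTR = −Σ p(l) ln p(l)`` over diagonal runs of length ≥ lmin;
      ``rENTR`` divides by ``ln(#distinct lengths)`` and is 0 when fewer
      than two distinct lengths occur.

    An empty matrix is not an error: all metrics are 0 and the result is
    flagged ``degenerate``.
    """
    if isinstance(R, np.ndarray):
        R = RecurrenceMatrix(R)
    total = R.n_recurrent
    if total == 0:
        return CRQAMetrics(rr=0.0, det=0.0, lam=0.0, maxl=0, rentr=0.0,
                           entr=0.0, n_recurrent=0, n_rows=R.n_rows,
                           n_cols=R.n_cols, params=params, degenerate=True)
    diag = diagonal_lines(R, lmin=1)
    vert = vertical_lines(R, vmin=1)
    rr = total / (R.n_rows * R.n_cols)
    det = sum(l * c for l, c in diag.items() if l >= lmin) / total
    lam = sum(v * c for v, c in vert.items() if v >= vmin) / total
    maxl = max(diag)
    counts = np.array([c for l, c in diag.items() if l >= lmin], dtype=float)
    if counts.size and counts.sum() > 0:
        p = counts / counts.sum()
        entr = float(-(p * np.log(p)).sum())
    else:
        entr = 0.0
    rentr = entr / np.log(counts.size) if counts.size > 1 else 0.0
    return CRQAMetrics(rr=float(rr), det=float(det), lam=float(lam),
                       maxl=int(maxl), rentr=float(rentr), entr=entr,
                       n_recurrent=total, n_rows=R.n_rows, n_cols=R.n_cols,
                       params=params)


# ---------------------------------------------------------------------------
# Embedding-parameter selection
# ---------------------------------------------------------------------------

def average_mutual_information(series: np.ndarray, max_lag: int,
                               n_bins: int = 10) -> np.ndarray:
    """AMI (nats) between the series and its lagged copy for lags 1..max_lag.

    Uses equiprobable binning (deciles by default), which makes the marginal
    entropies flat and the estimate robust to heavy-tailed amplitudes.
    """
    x = np.asarray(series, dtype=float).ravel()
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if len(x) <= max_lag + 1:
        raise ValueError(f"series of length {len(x)} too short for "
                         f"max_lag={max_lag}")
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    codes = np.searchsorted(edges, x)
    ami = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        a, b = codes[:-lag], codes[lag:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        ami[lag - 1] = (joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum()
    return ami


def select_delay(series: np.ndarray, max_lag: int = 40,
                 window: int = 2) -> int:
    """Embedding delay: first local minimum of AMI, else its global minimum.

    A lag counts as a local minimum when its AMI is the smallest within a
    ±``window`` neighbourhood, which keeps bin-resonance wiggles in the AMI
    curve from triggering spuriously early minima.
    """
    ami = average_mutual_information(series, max_lag)
    n = len(ami)
    for i in range(n - 1):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        if ami[i] == ami[lo:hi].min():
            return i + 1
    return int(np.argmin(ami)) + 1


def pair_delay(x: np.ndarray, y: np.ndarray, max_lag: int = 40) -> int:
    """Shared delay for a signal pair: the max of the individual choices.

    A single embedding must serve both members of the dyad; taking the max
    unfolds the slower of the two dynamics conservatively.
    """
    return max(select_delay(x, max_lag), select_delay(y, max_lag))


def false_nearest_neighbours(series: np.ndarray, delay: int, dim: int,
                             rtol: float = 10.0, atol: float = 2.0,
                             max_queries: int = 250) -> float:
    """Fraction of false nearest neighbours going from ``dim`` to ``dim+1``.

    Kennel's two criteria: a neighbour is false if the extra coordinate
    stretches the pair by more than ``rtol`` relative to its distance at
    ``dim``, or if the stretched distance exceeds ``atol`` attractor sizes
    (this second test is what keeps pure noise at a high FNN fraction).
    """
    x = np.asarray(series, dtype=float).ravel()
    r_attractor = x.std()
    if r_attractor == 0:
        raise DegenerateSignalError("constant series has no neighbours to test")
    X = embed(x, delay, dim)
    n_next = len(x) - dim * delay
    if n_next < 2:
        raise ValueError("series too short to test dimension "
                         f"{dim}+1 at delay {delay}")
    X = X[:n_next]
    nxt = x[dim * delay: dim * delay + n_next]
    # neighbours are sought in the full point set; for long series the FNN
    # fraction is estimated from an evenly spaced subset of query points
    if n_next > max_queries:
        q = np.linspace(0, n_next - 1, max_queries).astype(int)
    else:
        q = np.arange(n_next)
    dist, idx = cKDTree(X).query(X[q], k=2)
    nbr, d_m = idx[:, 1], dist[:, 1]
    # query-point index in the full set, neighbour index likewise
    self_hit = idx[:, 0] == q
    nbr = np.where(self_hit, idx[:, 1], idx[:, 0])
    d_m = np.where(self_hit, dist[:, 1], dist[:, 0])
    stretch = np.abs(nxt[q] - nxt[nbr])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_m > 0, stretch / np.maximum(d_m, 1e-300), np.inf)
    ratio[(d_m == 0) & (stretch == 0)] = 0.0
    d_m1 = np.sqrt(d_m ** 2 + stretch ** 2)
    false = (ratio > rtol) | (d_m1 / r_attractor > atol)
    # pairs separated by rounding error only are true neighbours, not false
    false &= d_m1 > 1e-9 * r_attractor
    return float(false.mean())


def select_dim(series: np.ndarray, delay: int, max_dim: int = 10,
               rtol: float = 10.0, threshold: float = 0.02) -> int:
    """Embedding dimension: smallest m with FNN fraction ≤ ``threshold``.

    Falls back to ``max_dim`` when the fraction never collapses (the
    signature of noise-dominated data).
    """
    for m in range(1, max_dim):
        if false_nearest_neighbours(series, delay, m, rtol=rtol) <= threshold:
            return m
    return max_dim


def pair_dim(x: np.ndarray, y: np.ndarray, delay: int, max_dim: int = 10,
             rtol: float = 10.0, threshold: float = 0.02) -> int:
    """Shared dimension for a pair: max of the individual choices."""
    return max(select_dim(x, delay, max_dim, rtol, threshold),
               select_dim(y, delay, max_dim, rtol, threshold))


def calibrate_radius(X_emb: np.ndarray, Y_emb: np.ndarray,
                     target_band: tuple[float, float] = (0.02, 0.04),
                     norm: str = "euclidean",
                     max_iter: int = 60,
                     distances: np.ndarray | None = None) -> tuple[float, float]:
    """Bisect the radius until the recurrence rate lands in ``target_band``.

    RR is monotone non-decreasing in the radius, so bisection on the
    midpoint of the band converges; iteration stops early once the achieved
    RR is within a small tolerance of the midpoint. Returns ``(radius,
    achieved_rr)`` or raises :class:`RadiusCalibrationError` (carrying the
    closest achievable RR) when ties in the distance distribution make the
    band unattainable.
    """
    X_emb, Y_emb = np.atleast_2d(X_emb), np.atleast_2d(Y_emb)
    if X_emb.shape[1] != Y_emb.shape[1]:
        raise ValueError("embedding dimension mismatch")
    D = cdist(X_emb, Y_emb, metric=_NORMS[norm]) if distances is None else distances
    target = 0.5 * (target_band[0] + target_band[1])
    tol = 0.05 * (target_band[1] - target_band[0])

    flat = D.ravel()
    if flat.size > 500_000:
        # bisect against a sorted deterministic subsample (every k-th
        # distance), then verify on the full matrix below
        step = flat.size // 250_000 + 1
        ref = np.sort(flat[::step])
    else:
        ref = np.sort(flat)

    def rr_ref(r: float) -> float:
        return np.searchsorted(ref, r, side="right") / ref.size

    lo, hi = 0.0, float(ref[-1])
    best_r = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rr = rr_ref(mid)
        if abs(rr - target) < abs(rr_ref(best_r) - target):
            best_r = mid
        if abs(rr - target) <= tol:
            break
        if rr < target:
            lo = mid
        else:
            hi = mid
    best_rr = float((flat <= best_r).mean())
    if not target_band[0] <= best_rr <= target_band[1]:
        # subsample estimate missed the band: re-bisect on the full matrix
        lo, hi = 0.0, float(D.max())
        best_r, best_rr = hi, float((flat <= hi).mean())
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            rr = float((flat <= mid).mean())
            if abs(rr - target) < abs(best_rr - target):
                best_r, best_rr = mid, rr
            if abs(rr - target) <= tol:
                break
            if rr < target:
                lo = mid
            else:
                hi = mid
    if target_band[0] <= best_rr <= target_band[1]:
        return best_r, best_rr
    raise RadiusCalibrationError(
        f"recurrence rate band {target_band} unattainable; closest achieved "
        f"RR = {best_rr:.4f} at radius {best_r:.4g}", best_rr, best_r)


# ---------------------------------------------------------------------------
# Full pipeline for one dyad-block
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRQAConfig:
    """Settings for the per-dyad CRQA pipeline."""

    target_band: tuple[float, float] = (0.02, 0.04)
    lmin: int = 2
    vmin: int = 2
    norm: str = "euclidean"
    max_lag: int = 40          # samples searched for the AMI minimum
    max_dim: int = 10
    rtol: float = 10.0
    fnn_threshold: float = 0.02


def run_crqa(demo_trace: SignalTrace | np.ndarray,
             obs_trace: SignalTrace | np.ndarray,
             cfg: CRQAConfig | None = None) -> CRQAMetrics:
    """Full CRQA for one dyad-block learning phase.

    Expects preprocessed (downsampled, z-scored) signals. Selects the shared
    delay (AMI, max over the pair) and dimension (FNN, max over the pair),
    embeds both signals, calibrates the radius to the target recurrence-rate
    band, and computes the metrics. All chosen parameters are recorded on
    the result. Calibration failures propagate as
    :class:`RadiusCalibrationError` so callers can exclude the dyad-block
    with a logged reason.
    """
    cfg = cfg or CRQAConfig()
    x = demo_trace.values if isinstance(demo_trace, SignalTrace) else np.asarray(demo_trace, float)
    y = obs_trace.values if isinstance(obs_trace, SignalTrace) else np.asarray(obs_trace, float)
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    max_lag = min(cfg.max_lag, n // 4)
    delay = pair_delay(x, y, max_lag=max_lag)
    dim = pair_dim(x, y, delay, max_dim=cfg.max_dim, rtol=cfg.rtol,
                   threshold=cfg.fnn_threshold)
    X_emb, Y_emb = embed(x, delay, dim), embed(y, delay, dim)
    D = cdist(X_emb, Y_emb, metric=_NORMS[cfg.norm])
    radius, achieved = calibrate_radius(X_emb, Y_emb, cfg.target_band,
                                        cfg.norm, distances=D)
    params = EmbeddingParams(delay=delay, dim=dim, radius=radius, norm=cfg.norm)
    R = RecurrenceMatrix(D <= radius)
    metrics = compute_metrics(R, lmin=cfg.lmin, vmin=cfg.vmin, params=params)
    metrics.extra["achieved_rr"] = achieved
    return metrics
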