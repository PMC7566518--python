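"""Nonparametric entropy and mutual-information estimators.

The workhorse is the Kozachenko-Leonenko k-nearest-neighbour differential
entropy estimator; mutual information is assembled from three entropy calls
(``I = h(X) + h(Y) - h(X, Y)``) with the same ``k`` throughout.  Two plug-in
histogram estimators (equal-width and equal-occupancy bins) serve as the
low-resolution comparators.  All values are in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

__all__ = [
    "EstimatorConfig",
    "knn_entropy",
    "knn_mi",
    "histogram_mi_fixed",
    "histogram_mi_adaptive",
    "sample_kurtosis",
    "estimate_mi",
    "resolve_k",
]

_METHODS = ("knn", "hist_fixed", "hist_adaptive")
_K_RULES = ("half_samples", "fixed")


@dataclass
class EstimatorConfig:
    """How mutual information is estimated from increment samples.

    ``k_rule = "half_samples"`` resolves ``k = floor(n / 2)`` at call time,
    the variance-oriented choice; ``"fixed"`` uses ``k_fixed`` (default 3,
    the bias-oriented choice).  ``n_bins`` applies to the histogram methods
    only; ``None`` resolves to 2 equal-width or 3 equal-occupancy bins.
    Negative k-NN estimates are reported raw unless ``clip_negative`` — raw
    values preserve the variance structure the benchmarks measure.
    ``jitter_scale > 0`` breaks exact duplicates with a deterministic uniform
    perturbation of ``jitter_scale * IQR * 1e-9`` per axis.
    """

    method: str = "knn"
    k_rule: str = "half_samples"
    k_fixed: int = 3
    n_bins: int | None = None
    clip_negative: bool = False
    jitter_scale: float = 0.0
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        if self.k_rule not in _K_RULES:
            raise ValueError(f"unknown k_rule {self.k_rule!r}; expected one of {_K_RULES}")
        if self.k_fixed < 1:
            raise ValueError("k_fixed must be at least 1")
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be non-negative")


def resolve_k(cfg: EstimatorConfig, n_samples: int) -> int:
    """The neighbour count the config implies for ``n_samples`` points."""
    k = n_samples // 2 if cfg.k_rule == "half_samples" else cfg.k_fixed
    return max(k, 1)


def _as_matrix(samples: np.ndarray) -> np.ndarray:
    a = np.asarray(samples, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("samples must be a vector or an (n, d) matrix")
    if not np.all(np.isfinite(a)):
        raise ValueError("samples must be finite")
    return a


def _apply_jitter(a: np.ndarray, scale: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    iqr = np.subtract(*np.percentile(a, [75, 25], axis=0))
    iqr = np.where(iqr > 0, iqr, 1.0)
    return a + rng.uniform(-1.0, 1.0, a.shape) * (scale * iqr * 1e-9)


def knn_entropy(
    samples: np.ndarray,
    k: int,
    jitter_scale: float = 0.0,
    jitter_seed: int = 0,
) -> float:
    """Kozachenko-Leonenko differential entropy in nats.

    ``h = psi(n) - psi(k) + log(c_d) + (d/n) * sum_i log eps_i`` with
    ``eps_i`` the Euclidean distance from point ``i`` to its k-th nearest
    neighbour and ``c_d`` the volume of the unit d-ball.  Exact duplicate
    points give ``eps = 0`` and raise unless jitter is enabled.
    """
    a = _as_matrix(samples)
    n, d = a.shape
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    if jitter_scale > 0:
        a = _apply_jitter(a, jitter_scale, jitter_seed)
    tree = cKDTree(a)
    eps, _ = tree.query(a, k=[k + 1])
    eps = eps[:, 0]
    if np.any(eps == 0.0):
        raise ValueError(
            "zero k-NN distance (duplicate points); enable jitter_scale to break ties"
        )
    log_cd = (d / 2.0) * np.log(np.pi) - gammaln(d / 2.0 + 1.0)
    return float(digamma(n) - digamma(k) + log_cd + d * np.mean(np.log(eps)))


def knn_mi(
    x_samples: np.ndarray,
    y_samples: np.ndarray,
    k: int,
    clip_negative: bool = False,
    jitter_scale: float = 0.0,
    jitter_seed: int = 0,
) -> float:
    """k-NN mutual information via three entropy calls with the same ``k``.

    May be negative for weakly dependent data when ``clip_negative`` is off.
    """
    x = _as_matrix(x_samples)
    y = _as_matrix(y_samples)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    kw = dict(jitter_scale=jitter_scale, jitter_seed=jitter_seed)
    mi = (
        knn_entropy(x, k, **kw)
        + knn_entropy(y, k, **kw)
        - knn_entropy(np.column_stack([x, y]), k, **kw)
    )
    return max(mi, 0.0) if clip_negative else mi


def _fixed_codes(a: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Equal-width bin codes per axis, combined into one joint cell index."""
    codes = np.zeros(a.shape[0], dtype=np.int64)
    n_cells = 1
    for j in range(a.shape[1]):
        col = a[:, j]
        lo, hi = col.min(), col.max()
        if lo == hi:
            warnings.warn(
                "constant axis in histogram MI: single occupied bin contributes 0",
                stacklevel=3,
            )
            axis_codes, nb = np.zeros(len(col), dtype=np.int64), 1
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
            axis_codes = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, n_bins - 1)
            nb = n_bins
        codes = codes * nb + axis_codes
        n_cells *= nb
    return codes, n_cells


def _adaptive_codes(a: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Equal-occupancy (quantile-edge) bin codes per axis."""
    codes = np.zeros(a.shape[0], dtype=np.int64)
    n_cells = 1
    for j in range(a.shape[1]):
        col = a[:, j]
        edges = np.quantile(col, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
        edges = np.unique(edges)
        if len(edges) < n_bins - 1:
            warnings.warn(
                "tied quantile edges in adaptive histogram MI: bins merged",
                stacklevel=3,
            )
        axis_codes = np.searchsorted(edges, col, side="right")
        nb = len(edges) + 1
        codes = codes * nb + axis_codes
        n_cells *= nb
    return codes, n_cells


def _plugin_mi(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in MI of two discrete code vectors in nats (0 log 0 = 0)."""
    n = len(cx)
    joint, counts = np.unique(np.column_stack([cx, cy]), axis=0, return_counts=True)
    pxy = counts / n
    _, ix = np.unique(cx, return_inverse=True)
    _, iy = np.unique(cy, return_inverse=True)
    px = np.bincount(ix) / n
    py = np.bincount(iy) / n
    _, jx = np.unique(joint[:, 0], return_inverse=True)
    _, jy = np.unique(joint[:, 1], return_inverse=True)
    mi = np.sum(pxy * (np.log(pxy) - np.log(px[jx]) - np.log(py[jy])))
    return float(max(mi, 0.0))


def histogram_mi_fixed(
    x_samples: np.ndarray, y_samples: np.ndarray, n_bins: int = 2
) -> float:
    """Plug-in MI with equal-width bins spanning each axis's observed range."""
    x, y = _as_matrix(x_samples), _as_matrix(y_samples)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    if x.shape[0] < n_bins:
        raise ValueError("need at least n_bins samples")
    cx, _ = _fixed_codes(x, n_bins)
    cy, _ = _fixed_codes(y, n_bins)
    return _plugin_mi(cx, cy)


def histogram_mi_adaptive(
    x_samples: np.ndarray, y_samples: np.ndarray, n_bins: int = 3
) -> float:
    """Plug-in MI with per-axis quantile bin edges (equal marginal occupancy).

    Invariant to monotone transforms of each axis, since only ranks enter.
    """
    x, y = _as_matrix(x_samples), _as_matrix(y_samples)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    if x.shape[0] < n_bins:
        raise ValueError("need at least n_bins samples")
    cx, _ = _adaptive_codes(x, n_bins)
    cy, _ = _adaptive_codes(y, n_bins)
    return _plugin_mi(cx, cy)


def sample_kurtosis(samples: np.ndarray) -> float:
    """Fourth standardized moment ``m4 / m2**2`` with biased central moments."""
    v = np.asarray(samples, dtype=float).ravel()
    if len(v) < 4:
        raise ValueError("need at least 4 samples")
    centered = v - v.mean()
    m2 = np.mean(centered**2)
    if m2 == 0.0:
        raise ValueError("zero variance")
    return float(np.mean(centered**4) / m2**2)


def estimate_mi(
    x_samples: np.ndarray,
    y_samples: np.ndarray,
    cfg: EstimatorConfig,
) -> float:
    """Dispatch MI estimation according to an :class:`EstimatorConfig`."""
    x = _as_matrix(x_samples)
    if cfg.method == "knn":
        k = resolve_k(cfg, x.shape[0])
        return knn_mi(
            x,
            y_samples,
            k,
            clip_negative=cfg.clip_negative,
            jitter_scale=cfg.jitter_scale,
            jitter_seed=cfg.jitter_seed,
        )
    if cfg.method == "hist_fixed":
        return histogram_mi_fixed(x, y_samples, n_bins=cfg.n_bins or 2)
    return histogram_mi_adaptive(x, y_samples, n_bins=cfg.n_bins or 3)
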