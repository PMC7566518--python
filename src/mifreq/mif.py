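"""Mutual information in frequency (MIF) under three taper-combination rules.

A complex increment sample enters the MI estimator as the 2-vector of its real
and imaginary parts, so MIF at a frequency pair is mutual information between
two 2-dimensional continuous variables.  With ``K`` tapers there are three
ways to combine the ``n_trials x K`` samples per channel:

* ``naive`` — pool all ``n_trials * K`` samples and estimate once;
* ``pre``   — average samples across tapers in the complex plane per trial,
  then estimate once from ``n_trials`` samples;
* ``post``  — estimate once per taper (``n_trials`` samples each) and average
  the ``K`` estimates.

For Gaussian process pairs, same-frequency MIF and coherence are linked by
``MI = -log(1 - C)``; the transform and its inverse are provided so coherence
pipelines can be read on the MIF scale (nats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimators import EstimatorConfig, estimate_mi, resolve_k
from .spectral import TaperSet, TrialWindowSet, frequency_to_bin, increment_matrix

__all__ = [
    "MIFMatrix",
    "STRATEGIES",
    "estimate_mif_at",
    "mif_matrix",
    "coherence_to_mif",
    "mif_to_coherence",
    "band_coupling",
]

STRATEGIES = ("naive", "pre", "post")


@dataclass
class MIFMatrix:
    """MI values in nats over a grid of frequency pairs ``(f_i, f_j)``."""

    freqs_x: np.ndarray
    freqs_y: np.ndarray
    values: np.ndarray
    strategy: str
    estimator: EstimatorConfig
    n_trials: int
    n_tapers: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MIF values must be finite")


def _c2r(z: np.ndarray) -> np.ndarray:
    """Complex vector -> (n, 2) matrix of [real, imag]."""
    z = np.asarray(z).ravel()
    return np.column_stack([z.real, z.imag])


def _mif_from_increments(
    dx: np.ndarray,
    dy: np.ndarray,
    cfg: EstimatorConfig,
    strategy: str,
) -> float:
    """Combine (n_trials, K) increment samples per the strategy and estimate."""
    n_trials, n_tapers = dx.shape
    if strategy == "pre":
        return estimate_mi(_c2r(dx.mean(axis=1)), _c2r(dy.mean(axis=1)), cfg)
    if strategy == "post":
        per_taper = [
            estimate_mi(_c2r(dx[:, k]), _c2r(dy[:, k]), cfg) for k in range(n_tapers)
        ]
        return float(np.mean(per_taper))
    if strategy == "naive":
        return estimate_mi(_c2r(dx.ravel()), _c2r(dy.ravel()), cfg)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def _check_sample_budget(cfg: EstimatorConfig, strategy: str, n_trials: int, n_tapers: int) -> None:
    n_eff = n_trials * n_tapers if strategy == "naive" else n_trials
    if cfg.method == "knn" and n_eff < resolve_k(cfg, n_eff) + 1:
        raise ValueError(
            f"{n_eff} samples are too few for k = {resolve_k(cfg, n_eff)} neighbours"
        )


def estimate_mif_at(
    x: TrialWindowSet,
    y: TrialWindowSet,
    f_i: float,
    f_j: float,
    tapers: TaperSet,
    cfg: EstimatorConfig | None = None,
    strategy: str = "post",
    demean: bool = True,
    nearest: bool = False,
) -> float:
    """MIF in nats between channel ``x`` at ``f_i`` and channel ``y`` at ``f_j``."""
    if cfg is None:
        cfg = EstimatorConfig()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if x.n_trials != y.n_trials:
        raise ValueError(f"trial counts differ: {x.n_trials} vs {y.n_trials}")
    _check_sample_budget(cfg, strategy, x.n_trials, tapers.n_tapers)
    mi = frequency_to_bin(f_i, x.n_samples, x.fs, nearest=nearest)
    mj = frequency_to_bin(f_j, y.n_samples, y.fs, nearest=nearest)
    dx = increment_matrix(x, tapers, bins=[mi], demean=demean)[:, :, 0]
    dy = increment_matrix(y, tapers, bins=[mj], demean=demean)[:, :, 0]
    return _mif_from_increments(dx, dy, cfg, strategy)


def mif_matrix(
    x: TrialWindowSet,
    y: TrialWindowSet,
    freqs_x: np.ndarray,
    freqs_y: np.ndarray,
    tapers: TaperSet,
    cfg: EstimatorConfig | None = None,
    strategy: str = "post",
    demean: bool = True,
) -> MIFMatrix:
    """MIF over all pairs of the two frequency grids.

    Increments are computed once per channel per frequency; element ``(i, j)``
    matches :func:`estimate_mif_at` at ``(freqs_x[i], freqs_y[j])``.
    """
    if cfg is None:
        cfg = EstimatorConfig()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if x.n_trials != y.n_trials:
        raise ValueError(f"trial counts differ: {x.n_trials} vs {y.n_trials}")
    _check_sample_budget(cfg, strategy, x.n_trials, tapers.n_tapers)
    freqs_x = np.atleast_1d(np.asarray(freqs_x, dtype=float))
    freqs_y = np.atleast_1d(np.asarray(freqs_y, dtype=float))
    bins_x = [frequency_to_bin(f, x.n_samples, x.fs) for f in freqs_x]
    bins_y = [frequency_to_bin(f, y.n_samples, y.fs) for f in freqs_y]
    dx = increment_matrix(x, tapers, bins=bins_x, demean=demean)
    dy = increment_matrix(y, tapers, bins=bins_y, demean=demean)
    values = np.empty((len(bins_x), len(bins_y)))
    for i in range(len(bins_x)):
        for j in range(len(bins_y)):
            values[i, j] = _mif_from_increments(dx[:, :, i], dy[:, :, j], cfg, strategy)
    return MIFMatrix(
        freqs_x=freqs_x,
        freqs_y=freqs_y,
        values=values,
        strategy=strategy,
        estimator=cfg,
        n_trials=x.n_trials,
        n_tapers=tapers.n_tapers,
    )


def coherence_to_mif(c: float | np.ndarray) -> float | np.ndarray:
    """Gaussian-process transform ``-log(1 - C)`` from coherence to nats.

    Coherence exactly 1 maps to ``+inf`` with a warning; values outside
    ``[0, 1]`` raise.
    """
    arr = np.asarray(c, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("coherence must lie in [0, 1]")
    if np.any(arr == 1.0):
        warnings.warn("coherence of 1 transforms to infinite MIF", stacklevel=2)
    with np.errstate(divide="ignore"):
        out = -np.log1p(-arr)
    return float(out) if np.isscalar(c) else out


def mif_to_coherence(mi: float | np.ndarray) -> float | np.ndarray:
    """Inverse Gaussian-process transform ``1 - exp(-MI)``."""
    arr = np.asarray(mi, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MIF must be non-negative for the coherence transform")
    out = -np.expm1(-arr)
    return float(out) if np.isscalar(mi) else out


def band_coupling(values: np.ndarray, mode: str = "mean") -> float:
    """Summarize per-bin coupling values over a frequency band.

    For MIF this is meant for the diagonal ``(f, f)`` values, which are
    commensurate with per-bin coherence.
    """
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}; only 'mean' is supported")
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty band")
    return float(arr.mean())
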