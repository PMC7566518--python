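"""Session-level statistics linking frequency coupling to task accuracy.

The analysis mirrors a trialized learning-session workflow: slide a window of
100 trials in steps of 10 across the session; within each trial window take
three short sub-windows of every trial (300 ms each, staggered starts),
estimate band coupling (coherence or diagonal MIF) in each sub-window and
average the three; significance-test the per-window values against a
max-statistic permutation null; and correlate the resulting coupling series
with per-window task accuracy using a circular moving-block bootstrap for
confidence intervals that respect the autocorrelation induced by the window
overlap.  A Z-test for two dependent correlations sharing the accuracy
variable compares coherence-based and MIF-based correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimators import EstimatorConfig
from .mif import _mif_from_increments
from .spectral import TaperSet, TrialWindowSet, generate_dpss, increment_matrix

__all__ = [
    "SlidingWindowPlan",
    "PermutationNull",
    "CorrelationResult",
    "SessionAnalysis",
    "sliding_trial_windows",
    "band_bins",
    "coupling_spectrum_series",
    "coupling_series",
    "permutation_max_threshold",
    "accuracy_series",
    "block_bootstrap_correlation",
    "dependent_correlation_ztest",
    "run_session_analysis",
]

_METHODS = ("coherence", "mif_post")


@dataclass
class SlidingWindowPlan:
    """Trial-window and sub-window geometry of the sliding analysis."""

    window_size: int = 100
    step: int = 10
    sub_window_starts: tuple[float, ...] = (1.6, 1.65, 1.7)
    sub_window_length: float = 0.3

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be at least 2")
        if self.step < 1:
            raise ValueError("step must be at least 1")
        if self.sub_window_length <= 0:
            raise ValueError("sub_window_length must be positive")
        if len(self.sub_window_starts) < 1:
            raise ValueError("need at least one sub-window start")


@dataclass
class PermutationNull:
    """Max-statistic permutation null distribution and its threshold."""

    n_permutations: int
    percentile: float
    null_max_samples: np.ndarray
    threshold: float
    seed: int


@dataclass
class CorrelationResult:
    """Pearson correlation with a block-bootstrap percentile interval."""

    r: float
    ci_low: float
    ci_high: float
    n_windows: int
    block_length: int
    n_bootstrap: int
    significant: bool


@dataclass
class SessionAnalysis:
    """Output of the end-to-end coupling-vs-accuracy pipeline."""

    windows: pd.DataFrame
    null: PermutationNull
    correlation: CorrelationResult
    method: str
    band: tuple[float, float]


def sliding_trial_windows(n_trials: int, plan: SlidingWindowPlan) -> list[tuple[int, int]]:
    """Half-open trial index ranges ``[start, start + window_size)``."""
    if n_trials < plan.window_size:
        raise ValueError(
            f"n_trials = {n_trials} is smaller than the window size {plan.window_size}"
        )
    n_windows = (n_trials - plan.window_size) // plan.step + 1
    return [(i * plan.step, i * plan.step + plan.window_size) for i in range(n_windows)]


def band_bins(n_samples: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """FFT bin indices whose center frequency lies in ``[low, high]`` inclusive."""
    freqs = np.arange(n_samples // 2 + 1) * (fs / n_samples)
    idx = np.nonzero((freqs >= band[0]) & (freqs <= band[1]))[0]
    if idx.size == 0:
        raise ValueError(
            f"band {band} contains no FFT bins at resolution {fs / n_samples} Hz"
        )
    return idx


def _sub_window(w: TrialWindowSet, start_s: float, length_s: float) -> TrialWindowSet:
    i0 = int(round((start_s - w.t0) * w.fs))
    n = int(round(length_s * w.fs))
    if i0 < 0 or i0 + n > w.n_samples:
        raise ValueError(
            f"sub-window [{start_s}, {start_s + length_s}) s falls outside the trial"
        )
    return TrialWindowSet(data=w.data[:, i0 : i0 + n], fs=w.fs, t0=start_s)


def _session_increments(
    x: TrialWindowSet,
    y: TrialWindowSet,
    plan: SlidingWindowPlan,
    band: tuple[float, float],
    tapers: TaperSet | None,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray, TaperSet]:
    """Per-sub-window increment arrays ``(n_trials, K, n_band_bins)``."""
    if x.n_trials != y.n_trials:
        raise ValueError("channels disagree on trial count")
    if x.fs != y.fs:
        raise ValueError("channels disagree on sampling rate")
    n_sub = int(round(plan.sub_window_length * x.fs))
    if tapers is None:
        tapers = generate_dpss(n_sub)
    bins = band_bins(n_sub, x.fs, band)
    dxs, dys = [], []
    for start in plan.sub_window_starts:
        xs = _sub_window(x, start, plan.sub_window_length)
        ys = _sub_window(y, start, plan.sub_window_length)
        dxs.append(increment_matrix(xs, tapers, bins=bins))
        dys.append(increment_matrix(ys, tapers, bins=bins))
    freqs = bins * (x.fs / n_sub)
    return dxs, dys, freqs, tapers


def _windowed_coherence(
    dx: np.ndarray, dy: np.ndarray, windows: list[tuple[int, int]]
) -> np.ndarray:
    """Per-window per-bin coherence from full-session increments.

    Cumulative sums over trials make every sliding window an O(1) slice.
    Shapes: increments ``(n_trials, K, B)`` -> result ``(n_windows, B)``.
    """
    px = np.abs(dx) ** 2
    py = np.abs(dy) ** 2
    pxy = dx * np.conj(dy)

    def wsum(a: np.ndarray) -> np.ndarray:
        c = np.concatenate([np.zeros((1, *a.shape[1:]), dtype=a.dtype), np.cumsum(a, axis=0)])
        return np.stack([c[b] - c[a_] for a_, b in windows])

    sx = wsum(px).sum(axis=1)
    sy = wsum(py).sum(axis=1)
    sxy = wsum(pxy).sum(axis=1)
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)


def _windowed_mif_post(
    dx: np.ndarray,
    dy: np.ndarray,
    windows: list[tuple[int, int]],
    cfg: EstimatorConfig,
) -> np.ndarray:
    out = np.empty((len(windows), dx.shape[2]))
    for w, (a, b) in enumerate(windows):
        for j in range(dx.shape[2]):
            out[w, j] = _mif_from_increments(dx[a:b, :, j], dy[a:b, :, j], cfg, "post")
    return out


def coupling_spectrum_series(
    x: TrialWindowSet,
    y: TrialWindowSet,
    plan: SlidingWindowPlan,
    band: tuple[float, float] = (4.0, 8.0),
    method: str = "coherence",
    cfg: EstimatorConfig | None = None,
    tapers: TaperSet | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window, per-band-bin coupling averaged over the sub-windows.

    Returns ``(values, frequencies)`` with ``values`` of shape
    ``(n_windows, n_band_bins)``.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    if cfg is None:
        cfg = EstimatorConfig()
    windows = sliding_trial_windows(x.n_trials, plan)
    dxs, dys, freqs, _ = _session_increments(x, y, plan, band, tapers)
    per_sub = []
    for dx, dy in zip(dxs, dys):
        if method == "coherence":
            per_sub.append(_windowed_coherence(dx, dy, windows))
        else:
            per_sub.append(_windowed_mif_post(dx, dy, windows, cfg))
    return np.mean(per_sub, axis=0), freqs


def coupling_series(
    x: TrialWindowSet,
    y: TrialWindowSet,
    plan: SlidingWindowPlan,
    band: tuple[float, float] = (4.0, 8.0),
    method: str = "coherence",
    cfg: EstimatorConfig | None = None,
    tapers: TaperSet | None = None,
) -> np.ndarray:
    """One band-mean coupling value per sliding trial window."""
    spectrum, _ = coupling_spectrum_series(x, y, plan, band, method, cfg, tapers)
    return spectrum.mean(axis=1)


def permutation_max_threshold(
    x: TrialWindowSet,
    y: TrialWindowSet,
    plan: SlidingWindowPlan,
    band: tuple[float, float] = (4.0, 8.0),
    method: str = "coherence",
    cfg: EstimatorConfig | None = None,
    tapers: TaperSet | None = None,
    n_permutations: int = 5000,
    percentile: float = 95.0,
    seed: int = 0,
) -> PermutationNull:
    """Max-statistic permutation null for the sliding-window coupling values.

    Each permutation shuffles the trial-to-trial pairing of the second
    channel across the whole session (each trial's waveform is preserved),
    recomputes the per-window per-bin coupling, and records the maximum over
    all windows and band bins.  The stated percentile of those maxima is the
    family-wise significance threshold.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    if cfg is None:
        cfg = EstimatorConfig()
    windows = sliding_trial_windows(x.n_trials, plan)
    dxs, dys, _, _ = _session_increments(x, y, plan, band, tapers)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(x.n_trials)
        per_sub = []
        for dx, dy in zip(dxs, dys):
            dyp = dy[perm]
            if method == "coherence":
                per_sub.append(_windowed_coherence(dx, dyp, windows))
            else:
                per_sub.append(_windowed_mif_post(dx, dyp, windows, cfg))
        maxima[p] = np.mean(per_sub, axis=0).max()
    threshold = float(np.percentile(maxima, percentile))
    return PermutationNull(
        n_permutations=n_permutations,
        percentile=percentile,
        null_max_samples=maxima,
        threshold=threshold,
        seed=seed,
    )


def accuracy_series(accuracy: np.ndarray, plan: SlidingWindowPlan) -> np.ndarray:
    """Fraction of correct trials per sliding trial window."""
    acc = np.asarray(accuracy, dtype=float).ravel()
    windows = sliding_trial_windows(len(acc), plan)
    return np.array([acc[a:b].mean() for a, b in windows])


def block_bootstrap_correlation(
    x_series: np.ndarray,
    y_series: np.ndarray,
    block_length: int | None = None,
    n_bootstrap: int = 2000,
    seed: int = 0,
    ci_level: float = 95.0,
) -> CorrelationResult:
    """Pearson correlation with a circular moving-block bootstrap interval.

    Blocks of consecutive windows are resampled jointly from both series
    (wrapping at the end), preserving the short-range autocorrelation that
    overlapping trial windows induce.  The default block length is
    ``ceil(n ** (1/3))``.
    """
    xs = np.asarray(x_series, dtype=float).ravel()
    ys = np.asarray(y_series, dtype=float).ravel()
    if xs.shape != ys.shape:
        raise ValueError("series lengths differ")
    n = len(xs)
    if n < 8:
        raise ValueError("need at least 8 windows to correlate")
    if xs.std() == 0.0 or ys.std() == 0.0:
        raise ValueError("zero-variance series")
    if block_length is None:
        block_length = int(math.ceil(n ** (1.0 / 3.0)))
    block_length = max(1, min(block_length, n))

    r = float(np.corrcoef(xs, ys)[0, 1])
    rng = np.random.default_rng(seed)
    n_blocks = int(math.ceil(n / block_length))
    reps = np.empty(n_bootstrap)
    offsets = np.arange(block_length)
    for b in range(n_bootstrap):
        starts = rng.integers(0, n, n_blocks)
        idx = ((starts[:, None] + offsets[None, :]) % n).ravel()[:n]
        xb, yb = xs[idx], ys[idx]
        if xb.std() == 0.0 or yb.std() == 0.0:
            reps[b] = 0.0
        else:
            reps[b] = np.corrcoef(xb, yb)[0, 1]
    alpha = (100.0 - ci_level) / 2.0
    lo, hi = np.percentile(reps, [alpha, 100.0 - alpha])
    return CorrelationResult(
        r=r,
        ci_low=float(lo),
        ci_high=float(hi),
        n_windows=n,
        block_length=block_length,
        n_bootstrap=n_bootstrap,
        significant=bool(lo > 0.0 or hi < 0.0),
    )


def dependent_correlation_ztest(
    r1: float, r2: float, r_between: float, n: int
) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin Z-test for two correlations sharing one variable.

    ``r1`` and ``r2`` each correlate a predictor with the same outcome and
    ``r_between`` is the correlation of the two predictors.  Returns
    ``(z, two_tailed_p)``; the sign of ``z`` follows ``r1 - r2``.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r_between", r_between)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n < 4:
        raise ValueError("n must be at least 4")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    r_sq_bar = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r_between) / (2.0 * (1.0 - r_sq_bar)), 1.0)
    h = (1.0 - f * r_sq_bar) / (1.0 - r_sq_bar)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r_between) * h))
    p = 2.0 * float(norm.sf(abs(z)))
    return z, min(p, 1.0)


def run_session_analysis(
    x: TrialWindowSet,
    y: TrialWindowSet,
    accuracy: np.ndarray,
    plan: SlidingWindowPlan | None = None,
    band: tuple[float, float] = (4.0, 8.0),
    method: str = "coherence",
    cfg: EstimatorConfig | None = None,
    tapers: TaperSet | None = None,
    n_permutations: int = 5000,
    gate: str = "zero",
    block_length: int | None = None,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> SessionAnalysis:
    """End-to-end pipeline: coupling series, significance gate, correlation.

    A trial window passes the significance gate when the maximum of its
    band-bin couplings exceeds the permutation threshold.  With
    ``gate="zero"`` the band coupling of failing windows is set to 0 before
    correlating with accuracy; ``gate="keep"`` retains raw values.
    """
    if gate not in ("zero", "keep"):
        raise ValueError("gate must be 'zero' or 'keep'")
    if len(np.asarray(accuracy).ravel()) != x.n_trials:
        raise ValueError("accuracy length must match the trial count")
    if plan is None:
        plan = SlidingWindowPlan()
    ss = np.random.SeedSequence(seed)
    seed_perm, seed_boot = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(2))

    spectrum, _ = coupling_spectrum_series(x, y, plan, band, method, cfg, tapers)
    coupling = spectrum.mean(axis=1)
    null = permutation_max_threshold(
        x, y, plan, band, method, cfg, tapers,
        n_permutations=n_permutations, seed=seed_perm,
    )
    passed = spectrum.max(axis=1) > null.threshold
    gated = np.where(passed, coupling, 0.0) if gate == "zero" else coupling
    acc = accuracy_series(accuracy, plan)
    corr = block_bootstrap_correlation(
        gated, acc, block_length=block_length, n_bootstrap=n_bootstrap, seed=seed_boot
    )
    windows = sliding_trial_windows(x.n_trials, plan)
    table = pd.DataFrame(
        dict(
            window_start_trial=[a for a, _ in windows],
            coupling=coupling,
            coupling_gated=gated,
            accuracy=acc,
            passed_threshold=passed,
        )
    )
    return SessionAnalysis(
        windows=table, null=null, correlation=corr, method=method, band=band
    )
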