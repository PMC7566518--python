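"""Multitaper spectral machinery: DPSS tapers, Fourier increments, coherence.

The estimation pipeline works on *trialized* data: a real matrix of shape
``(n_trials, n_samples)`` with a sampling rate.  Each trial window is
multiplied element-wise by each of ``K`` orthonormal Slepian (DPSS) tapers and
Fourier-transformed, yielding one complex *increment sample* per
``(trial, taper)`` pair at each FFT-bin frequency.  Power and cross spectra
average ``|dX|^2`` and ``dX conj(dY)`` over trials and tapers; magnitude
squared coherence is ``|S_XY|^2 / (S_X S_Y)``.

Increments use the normalization ``FFT / N``.  Coherence is invariant to this
choice (and to any per-channel rescaling); it is fixed only so that increment
values are reproducible across machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as _windows

__all__ = [
    "TrialWindowSet",
    "TaperSet",
    "IncrementSamples",
    "CoherenceSpectrum",
    "generate_dpss",
    "hamming_taper",
    "condition_windows",
    "fft_bin_frequencies",
    "frequency_to_bin",
    "fourier_increment_samples",
    "increment_matrix",
    "multitaper_spectra",
    "estimate_coherence",
]


@dataclass
class TrialWindowSet:
    """Trials-by-samples real matrix with its sampling rate.

    ``t0`` is the window start time relative to the trial reference (e.g.
    stimulus onset), used when slicing sub-windows out of longer trials.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (trials x samples) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TaperSet:
    """Orthonormal taper matrix ``(K, N)`` with concentration eigenvalues.

    ``nw`` is the time-half-bandwidth product for DPSS tapers and ``None`` for
    the single-taper Hamming comparator, which has no concentration design.
    """

    tapers: np.ndarray
    nw: float | None
    concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tapers = np.atleast_2d(np.asarray(self.tapers, dtype=float))
        gram = self.tapers @ self.tapers.T
        if not np.allclose(gram, np.eye(self.tapers.shape[0]), atol=1e-8):
            raise ValueError("taper rows must be orthonormal (within 1e-8)")

    @property
    def n_tapers(self) -> int:
        return self.tapers.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tapers.shape[1]


@dataclass
class IncrementSamples:
    """Complex Fourier increment samples at one frequency.

    ``values`` has shape ``(n_trials, n_tapers)``; entry ``(i, k)`` is the
    normalized Fourier coefficient of trial ``i`` under taper ``k``.
    """

    frequency: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=complex))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("increment samples must be finite")


@dataclass
class CoherenceSpectrum:
    """Per-frequency spectra and magnitude-squared coherence."""

    frequencies: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    sxy: np.ndarray
    coherence: np.ndarray


def generate_dpss(
    n_samples: int,
    nw: float = 2.0,
    n_tapers: int | None = None,
    allow_extra: bool = False,
) -> TaperSet:
    """Discrete prolate spheroidal (Slepian) tapers with unit energy.

    Tapers are ordered by decreasing spectral concentration in the design
    band of half-width ``nw * fs / n_samples``.  At most ``floor(2 nw) - 1``
    tapers are well concentrated; requesting more raises unless
    ``allow_extra`` is set.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    k_max = int(math.floor(2 * nw)) - 1
    if n_tapers is None:
        n_tapers = k_max
    if n_tapers < 1:
        raise ValueError("n_tapers must be at least 1")
    if n_tapers > k_max and not allow_extra:
        raise ValueError(
            f"n_tapers = {n_tapers} exceeds the concentration limit "
            f"floor(2*nw) - 1 = {k_max}; pass allow_extra=True to override"
        )
    tapers, ratios = _windows.dpss(n_samples, nw, Kmax=n_tapers, return_ratios=True)
    return TaperSet(tapers=tapers, nw=nw, concentrations=np.atleast_1d(ratios))


def hamming_taper(n_samples: int) -> TaperSet:
    """Single Hamming window normalized to unit energy.

    The traditional single-taper comparator: one spectral estimate per trial
    instead of ``K`` quasi-independent ones.
    """
    w = _windows.hamming(n_samples, sym=False)
    w = w / np.linalg.norm(w)
    return TaperSet(tapers=w[None, :], nw=None, concentrations=None)


def condition_windows(w: TrialWindowSet) -> TrialWindowSet:
    """Remove each trial's mean so the DC bin cannot leak into low bins."""
    data = w.data - w.data.mean(axis=1, keepdims=True)
    return TrialWindowSet(data=data, fs=w.fs, t0=w.t0)


def fft_bin_frequencies(n_samples: int, fs: float) -> np.ndarray:
    """The one-sided FFT frequency grid ``fs * m / N`` for ``m = 0 .. N//2``."""
    return np.arange(n_samples // 2 + 1) * (fs / n_samples)


def frequency_to_bin(
    frequency: float, n_samples: int, fs: float, nearest: bool = False
) -> int:
    """Map a frequency in Hz to its one-sided FFT bin index.

    Off-grid frequencies raise unless ``nearest`` is set, in which case the
    closest bin is used.
    """
    m = frequency * n_samples / fs
    m_round = int(round(m))
    if not nearest and abs(m - m_round) > 1e-9:
        raise ValueError(
            f"frequency {frequency} Hz is not on the FFT grid "
            f"(bin spacing {fs / n_samples} Hz); pass nearest=True to snap"
        )
    m_round = min(max(m_round, 0), n_samples // 2)
    return m_round


def increment_matrix(
    w: TrialWindowSet,
    tapers: TaperSet,
    bins: np.ndarray | list[int] | None = None,
    demean: bool = True,
) -> np.ndarray:
    """Increment samples for every requested bin at once.

    Returns a complex array of shape ``(n_trials, n_tapers, n_bins)`` holding
    ``(1/N) sum_n taper[n] * x[trial, n] * exp(-2j pi m n / N)``.
    """
    if tapers.n_samples != w.n_samples:
        raise ValueError(
            f"taper length {tapers.n_samples} does not match window length {w.n_samples}"
        )
    if demean:
        w = condition_windows(w)
    n = w.n_samples
    tapered = w.data[:, None, :] * tapers.tapers[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1) / n
    if bins is None:
        return spec
    return spec[:, :, np.asarray(bins, dtype=int)]


def fourier_increment_samples(
    w: TrialWindowSet,
    tapers: TaperSet,
    frequency: float,
    nearest: bool = False,
    demean: bool = True,
) -> IncrementSamples:
    """Complex increment samples of one channel at one on-grid frequency."""
    m = frequency_to_bin(frequency, w.n_samples, w.fs, nearest=nearest)
    values = increment_matrix(w, tapers, bins=[m], demean=demean)[:, :, 0]
    return IncrementSamples(frequency=m * w.fs / w.n_samples, values=values)


def multitaper_spectra(
    x: TrialWindowSet,
    y: TrialWindowSet,
    tapers: TaperSet | None = None,
    frequencies: np.ndarray | None = None,
    demean: bool = True,
) -> CoherenceSpectrum:
    """Multitaper power/cross spectra and coherence on the FFT bin grid.

    Spectral estimates average over all ``(trial, taper)`` pairs:
    ``S_X = mean |dX|^2``, ``S_XY = mean dX conj(dY)``, and
    ``C_XY = |S_XY|^2 / (S_X S_Y)`` per bin (zero-power bins report 0).
    """
    if x.n_trials != y.n_trials:
        raise ValueError(f"trial counts differ: {x.n_trials} vs {y.n_trials}")
    if x.fs != y.fs:
        raise ValueError(f"sampling rates differ: {x.fs} vs {y.fs}")
    if x.n_samples != y.n_samples:
        raise ValueError("window lengths differ between channels")
    if tapers is None:
        tapers = generate_dpss(x.n_samples)

    if frequencies is None:
        bins = np.arange(x.n_samples // 2 + 1)
    else:
        bins = np.array(
            [frequency_to_bin(f, x.n_samples, x.fs) for f in np.atleast_1d(frequencies)]
        )
    dx = increment_matrix(x, tapers, bins=bins, demean=demean)
    dy = increment_matrix(y, tapers, bins=bins, demean=demean)

    sx = np.mean(np.abs(dx) ** 2, axis=(0, 1))
    sy = np.mean(np.abs(dy) ** 2, axis=(0, 1))
    sxy = np.mean(dx * np.conj(dy), axis=(0, 1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)
    return CoherenceSpectrum(
        frequencies=bins * (x.fs / x.n_samples),
        sx=sx,
        sy=sy,
        sxy=sxy,
        coherence=coherence,
    )


def estimate_coherence(
    x: TrialWindowSet,
    y: TrialWindowSet,
    tapers: TaperSet | None = None,
    frequencies: np.ndarray | None = None,
    demean: bool = True,
) -> CoherenceSpectrum:
    """Convenience wrapper for :func:`multitaper_spectra`."""
    return multitaper_spectra(x, y, tapers=tapers, frequencies=frequencies, demean=demean)
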