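"""Random-sinusoid models and synthetic task sessions.

Two families of band-limited stochastic processes are provided, both of the
form ``X(t) = A cos(2 pi f0 t + Theta)`` with a fresh amplitude/phase draw per
sample path (trial):

* ``rayleigh`` — ``A ~ Rayleigh(1)``.  With uniform phase this makes ``X(t)``
  a Gaussian process concentrated at the single frequency ``f0``.  A second
  channel ``Y = X + W`` adds an independent disturbance of the same form with
  ``B ~ Rayleigh(sigma_b)``, for which the mutual information in frequency at
  ``(f0, f0)`` is known in closed form: ``log(1 + 1/sigma_b**2)`` nats.
* ``uniform`` — ``A ~ Uniform(-h, h)``.  The marginal is no longer Gaussian
  (its kurtosis is 2.7 at any half-width), which is the non-Gaussian test bed
  on which coherence provably misses dependence that mutual information sees.

All information quantities in this package are in nats (natural logarithms).

A task-session generator produces two channels whose narrow-band coupling
drifts across trials together with a per-trial binary accuracy outcome linked
to that coupling, emulating the structure of a learning session of trialized
local-field-potential recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectral import TrialWindowSet

__all__ = [
    "SinusoidModelParams",
    "TaskSessionParams",
    "simulate_random_sinusoids",
    "simulate_marginal",
    "simulate_task_session",
    "true_mif_gp",
    "sigma_b_for_true_mif",
    "analytic_kurtosis",
]

_FAMILIES = ("rayleigh", "uniform")


@dataclass
class SinusoidModelParams:
    """Parameters of the random-sinusoid pair ``(X, Y = X + W)``.

    Parameters
    ----------
    f0 : float
        Oscillation frequency in Hz.  Must lie below the Nyquist rate.
    fs : float
        Sampling rate in Hz.
    n_samples : int
        Samples per path.  The default geometry (128 samples at 128 Hz with
        ``f0 = 8``) puts ``f0`` exactly on an FFT bin.
    n_paths : int
        Number of independent sample paths (trials).
    sigma_b : float
        Rayleigh scale of the disturbance amplitude ``B`` (GP family).
    amplitude_family : {"rayleigh", "uniform"}
        Distribution of the amplitudes ``A`` and ``B``.
    uniform_halfwidth : float
        Half-width ``h`` of ``Uniform(-h, h)`` amplitudes (uniform family).
    seed : int or None
        Seed for the generator; ``None`` draws fresh entropy.
    """

    f0: float = 8.0
    fs: float = 128.0
    n_samples: int = 128
    n_paths: int = 100
    sigma_b: float = 1.0
    amplitude_family: str = "rayleigh"
    uniform_halfwidth: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amplitude_family not in _FAMILIES:
            raise ValueError(
                f"unknown amplitude_family {self.amplitude_family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if not self.f0 < self.fs / 2:
            raise ValueError(f"f0 = {self.f0} Hz must lie below Nyquist {self.fs / 2} Hz")
        if self.n_samples < 8:
            raise ValueError("n_samples must be at least 8")
        if self.n_paths < 2:
            raise ValueError("n_paths must be at least 2")
        if self.amplitude_family == "rayleigh" and not self.sigma_b > 0:
            raise ValueError("sigma_b must be positive for the rayleigh family")
        if self.uniform_halfwidth <= 0:
            raise ValueError("uniform_halfwidth must be positive")


def _draw_amplitudes(params: SinusoidModelParams, scale: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    if params.amplitude_family == "rayleigh":
        return rng.rayleigh(scale, n)
    return rng.uniform(-params.uniform_halfwidth, params.uniform_halfwidth, n)


def simulate_random_sinusoids(
    params: SinusoidModelParams,
    rng: np.random.Generator | None = None,
) -> tuple[TrialWindowSet, TrialWindowSet]:
    """Draw sample paths of ``X`` and ``Y = X + W``.

    Each path draws its own mutually independent ``(A, Theta, B, Phi)``; there
    are no within-path amplitude dynamics.  Returns two trial-window sets of
    shape ``(n_paths, n_samples)`` sharing the sampling rate.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_paths
    t = np.arange(params.n_samples) / params.fs
    a = _draw_amplitudes(params, 1.0, n, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    b = _draw_amplitudes(params, params.sigma_b, n, rng)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    arg = 2.0 * np.pi * params.f0 * t
    x = a[:, None] * np.cos(arg + theta[:, None])
    w = b[:, None] * np.cos(arg + phi[:, None])
    return (
        TrialWindowSet(data=x, fs=params.fs),
        TrialWindowSet(data=x + w, fs=params.fs),
    )


def simulate_marginal(
    params: SinusoidModelParams,
    n_draws: int,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> np.ndarray:
    """Independent draws of the marginal ``X(t0)`` of the primary channel.

    Because the phase is uniform the marginal law does not depend on ``t0``;
    the argument exists so the stationarity can be exercised directly.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    a = _draw_amplitudes(params, 1.0, n_draws, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_draws)
    return a * np.cos(2.0 * np.pi * params.f0 * t0 + theta)


def true_mif_gp(sigma_b: float) -> float:
    """Closed-form MIF at ``(f0, f0)`` of the Gaussian sinusoid pair, in nats.

    ``log(1 + 1/sigma_b**2)``: the information a noisy copy ``Y = X + W``
    carries about ``X`` at the oscillation frequency, with ``sigma_b`` the
    Rayleigh scale of the disturbance amplitude.
    """
    if not sigma_b > 0:
        raise ValueError("sigma_b must be positive")
    return math.log1p(1.0 / sigma_b**2)


def sigma_b_for_true_mif(mi: float) -> float:
    """Disturbance scale whose Gaussian-model MIF equals ``mi`` nats."""
    if not mi > 0:
        raise ValueError("mi must be positive")
    return 1.0 / math.sqrt(math.expm1(mi))


def analytic_kurtosis(amplitude_family: str, uniform_halfwidth: float = 0.5) -> float:
    """Fourth standardized moment of the model marginal ``A cos(phase)``.

    Evaluated from the factorized moments of amplitude and phase:
    ``E[X^4] / E[X^2]^2`` with ``E[cos^2] = 1/2`` and ``E[cos^4] = 3/8``.
    Rayleigh amplitudes give exactly 3 (the Gaussian value) for any scale;
    uniform amplitudes give 27/10 for any half-width.
    """
    cos2, cos4 = 0.5, 3.0 / 8.0
    if amplitude_family == "rayleigh":
        # E[A^2] = 2 s^2, E[A^4] = 8 s^4 for Rayleigh(s); scale cancels.
        a2, a4 = 2.0, 8.0
    elif amplitude_family == "uniform":
        h = uniform_halfwidth
        a2, a4 = h**2 / 3.0, h**4 / 5.0
    else:
        raise ValueError(f"unknown amplitude_family {amplitude_family!r}")
    return (a4 * cos4) / (a2 * cos2) ** 2


@dataclass
class TaskSessionParams:
    """Parameters of the synthetic two-channel task session.

    The two channels share a narrow-band random-phase sinusoid whose per-trial
    strength follows ``coupling_profile``; each channel adds independent
    broadband noise.  Per-trial success is Bernoulli with a logistic link from
    the trial's coupling strength, so sessions with drifting coupling carry a
    built-in coupling-accuracy association.
    """

    n_trials: int = 400
    fs: float = 200.0
    trial_length_s: float = 3.6
    band: tuple[float, float] = (4.0, 8.0)
    coupling_profile: np.ndarray | None = None
    accuracy_link: float = 6.0
    base_accuracy: float = 0.75
    seed: int | None = None
    # Resolved in __post_init__ when coupling_profile is None: a linear ramp,
    # the simplest trajectory with the monotone drift of a learning session.
    profile_range: tuple[float, float] = (0.15, 0.85)

    def __post_init__(self) -> None:
        if self.n_trials < 120:
            raise ValueError("n_trials must be at least 120 (100-trial windows downstream)")
        lo, hi = self.band
        if not (0.0 < lo < hi < self.fs / 2):
            raise ValueError(f"band {self.band} must lie strictly inside (0, fs/2)")
        if self.coupling_profile is None:
            self.coupling_profile = np.linspace(*self.profile_range, self.n_trials)
        self.coupling_profile = np.asarray(self.coupling_profile, dtype=float)
        if self.coupling_profile.shape != (self.n_trials,):
            raise ValueError("coupling_profile must have one value per trial")
        if np.any(self.coupling_profile < 0) or np.any(self.coupling_profile >= 1):
            raise ValueError("coupling_profile values must lie in [0, 1)")


def simulate_task_session(
    params: TaskSessionParams,
    rng: np.random.Generator | None = None,
) -> tuple[TrialWindowSet, TrialWindowSet, np.ndarray]:
    """Generate two coupled channels and a per-trial binary accuracy series.

    Returns ``(x, y, accuracy)`` with ``x.data`` of shape
    ``(n_trials, round(trial_length_s * fs))`` and ``accuracy`` a 0/1 vector.
    Trial ``i`` mixes a shared unit-variance sinusoid at the band centre with
    weight ``sqrt(c_i)`` and private white noise with weight ``sqrt(1 - c_i)``,
    so the band coupling increases monotonically with ``c_i`` and vanishes at
    ``c_i = 0``.  ``P(correct_i)`` is logistic in ``c_i`` centred on the
    session-mean coupling, with slope ``accuracy_link`` and intercept set by
    ``base_accuracy``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    c = params.coupling_profile
    n_t = int(round(params.trial_length_s * params.fs))
    t = np.arange(n_t) / params.fs
    f_c = 0.5 * (params.band[0] + params.band[1])

    phase = rng.uniform(0.0, 2.0 * np.pi, params.n_trials)
    shared = math.sqrt(2.0) * np.cos(2.0 * np.pi * f_c * t + phase[:, None])
    amp = np.sqrt(c)[:, None]
    noise_amp = np.sqrt(1.0 - c)[:, None]
    x = amp * shared + noise_amp * rng.standard_normal((params.n_trials, n_t))
    y = amp * shared + noise_amp * rng.standard_normal((params.n_trials, n_t))

    logit_base = math.log(params.base_accuracy / (1.0 - params.base_accuracy))
    eta = logit_base + params.accuracy_link * (c - c.mean())
    p_correct = 1.0 / (1.0 + np.exp(-eta))
    accuracy = (rng.random(params.n_trials) < p_correct).astype(int)

    return (
        TrialWindowSet(data=x, fs=params.fs),
        TrialWindowSet(data=y, fs=params.fs),
        accuracy,
    )
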