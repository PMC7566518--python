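"""Monte-Carlo benchmarks of the MIF estimators on the Gaussian sinusoid model.

Three experiment designs, all with known ground truth through the closed-form
``log(1 + 1/sigma_b**2)``:

* *correlation sweeps* — truths drawn uniformly in a band around each center,
  Pearson correlation between estimates and truths per estimator (the figure
  of merit for coupling-vs-behaviour studies: an estimator's measurable
  correlation is capped by its variance, not its bias);
* *variance curves* — truth held fixed per center, estimator variance across
  repetitions;
* *asymptotics* — estimate distributions across sample sizes for the
  bias-oriented pre estimator (k = 3) and the variance-oriented post
  estimator (k = n/2).

Variances are comparable only across taper strategies within one MI-estimator
family: a constant estimator has zero variance and zero correlation with
truth, so variance alone ranks nothing across families.

Full-scale runs (1e4 repetitions) are a parameter away; the defaults are
scaled to minutes on one CPU and are meant to be read through orderings and
bootstrap intervals rather than through third-decimal values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .estimators import EstimatorConfig
from .mif import _mif_from_increments
from .simulate import SinusoidModelParams, sigma_b_for_true_mif, simulate_random_sinusoids
from .spectral import TaperSet, frequency_to_bin, generate_dpss, hamming_taper, increment_matrix

__all__ = [
    "EstimatorSpec",
    "BenchmarkResult",
    "default_estimator_specs",
    "run_correlation_benchmark",
    "run_variance_benchmark",
    "run_asymptotic_benchmark",
]


@dataclass(frozen=True)
class EstimatorSpec:
    """One estimator column of a benchmark: taper scheme x strategy x config."""

    label: str
    strategy: str
    estimator: EstimatorConfig
    taper: str = "dpss"  # "dpss" or "hamming"
    nw: float = 2.0
    n_tapers: int = 3

    def build_tapers(self, n_samples: int) -> TaperSet:
        if self.taper == "hamming":
            return hamming_taper(n_samples)
        if self.taper == "dpss":
            return generate_dpss(n_samples, nw=self.nw, n_tapers=self.n_tapers)
        raise ValueError(f"unknown taper scheme {self.taper!r}")


@dataclass
class BenchmarkResult:
    """Summary row of one benchmark cell."""

    center_true_mi: float
    label: str
    strategy: str
    family: str
    n_reps: int
    correlation_with_truth: float
    estimator_variance: float
    seed: int
    degenerate: bool = False


def default_estimator_specs() -> list[EstimatorSpec]:
    """k-NN under the three taper strategies plus the Hamming single taper.

    All use the half-the-samples neighbour rule, the variance-oriented
    default of the estimator-comparison experiments.
    """
    knn = EstimatorConfig(method="knn", k_rule="half_samples")
    return [
        EstimatorSpec("knn-naive", "naive", knn),
        EstimatorSpec("knn-pre", "pre", knn),
        EstimatorSpec("knn-post", "post", knn),
        EstimatorSpec("knn-hamming", "pre", knn, taper="hamming"),
    ]


def _evaluate_specs(
    x, y, bin_f0: int, specs: list[EstimatorSpec], taper_cache: dict
) -> list[float]:
    """All spec estimates at (f0, f0) on one simulated path set (paired)."""
    out = []
    inc_cache: dict = {}
    for spec in specs:
        key = (spec.taper, spec.nw, spec.n_tapers)
        if key not in taper_cache:
            taper_cache[key] = spec.build_tapers(x.n_samples)
        tapers = taper_cache[key]
        if key not in inc_cache:
            dx = increment_matrix(x, tapers, bins=[bin_f0])[:, :, 0]
            dy = increment_matrix(y, tapers, bins=[bin_f0])[:, :, 0]
            inc_cache[key] = (dx, dy)
        dx, dy = inc_cache[key]
        out.append(_mif_from_increments(dx, dy, spec.estimator, spec.strategy))
    return out


def _summaries(
    estimates: pd.DataFrame, specs: list[EstimatorSpec], center: float,
    n_reps: int, seed: int,
) -> list[BenchmarkResult]:
    rows = []
    for spec in specs:
        sub = estimates[(estimates["label"] == spec.label) & (estimates["center"] == center)]
        est = sub["estimate"].to_numpy()
        truth = sub["truth"].to_numpy()
        degenerate = np.ptp(est) == 0.0 or np.ptp(truth) == 0.0
        rho = 0.0 if degenerate else float(np.corrcoef(truth, est)[0, 1])
        rows.append(
            BenchmarkResult(
                center_true_mi=center,
                label=spec.label,
                strategy=spec.strategy,
                family=spec.estimator.method,
                n_reps=n_reps,
                correlation_with_truth=rho,
                estimator_variance=float(est.var()),
                seed=seed,
                degenerate=degenerate,
            )
        )
    return rows


def _results_frame(rows: list[BenchmarkResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def run_correlation_benchmark(
    centers: list[float] | np.ndarray = (1.0,),
    half_range: float = 0.2,
    n_reps: int = 300,
    n_paths: int = 100,
    specs: list[EstimatorSpec] | None = None,
    model: SinusoidModelParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation between estimates and truths drawn around each center.

    Per repetition a true MIF is drawn uniformly in
    ``[center - half_range, center + half_range]``, the matching
    ``sigma_b`` is derived, ``n_paths`` paths are simulated once, and every
    spec is evaluated on the same paths (paired columns).  Returns
    ``(summary, estimates)`` data frames; a constant estimator reports
    correlation 0 with ``degenerate=True``.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be at least 10 for a meaningful correlation")
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if np.any(centers - half_range <= 0):
        raise ValueError("centers - half_range must stay positive")
    if specs is None:
        specs = default_estimator_specs()
    if model is None:
        model = SinusoidModelParams(n_paths=n_paths)
    else:
        model = replace(model, n_paths=n_paths)
    bin_f0 = frequency_to_bin(model.f0, model.n_samples, model.fs)

    taper_cache: dict = {}
    records = []
    ss = np.random.SeedSequence(seed)
    for center in centers:
        rngs = [np.random.default_rng(s) for s in ss.spawn(n_reps)]
        for rep, rng in enumerate(rngs):
            truth = rng.uniform(center - half_range, center + half_range)
            m = replace(model, sigma_b=sigma_b_for_true_mif(truth))
            x, y = simulate_random_sinusoids(m, rng=rng)
            for spec, est in zip(specs, _evaluate_specs(x, y, bin_f0, specs, taper_cache)):
                records.append(
                    dict(center=center, rep=rep, truth=truth, label=spec.label, estimate=est)
                )
    estimates = pd.DataFrame.from_records(records)
    rows = [r for c in centers for r in _summaries(estimates, specs, c, n_reps, seed)]
    return _results_frame(rows), estimates


def run_variance_benchmark(
    centers: list[float] | np.ndarray = (1.0,),
    n_reps: int = 300,
    n_paths: int = 100,
    specs: list[EstimatorSpec] | None = None,
    model: SinusoidModelParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimator variance across repetitions at fixed truths (no range)."""
    if n_reps < 10:
        raise ValueError("n_reps must be at least 10 for a meaningful variance")
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if np.any(centers <= 0):
        raise ValueError("centers must be positive")
    if specs is None:
        specs = default_estimator_specs()
    if model is None:
        model = SinusoidModelParams(n_paths=n_paths)
    else:
        model = replace(model, n_paths=n_paths)
    bin_f0 = frequency_to_bin(model.f0, model.n_samples, model.fs)

    taper_cache: dict = {}
    records = []
    ss = np.random.SeedSequence(seed)
    for center in centers:
        m = replace(model, sigma_b=sigma_b_for_true_mif(float(center)))
        rngs = [np.random.default_rng(s) for s in ss.spawn(n_reps)]
        for rep, rng in enumerate(rngs):
            x, y = simulate_random_sinusoids(m, rng=rng)
            for spec, est in zip(specs, _evaluate_specs(x, y, bin_f0, specs, taper_cache)):
                records.append(
                    dict(center=center, rep=rep, truth=float(center), label=spec.label,
                         estimate=est)
                )
    estimates = pd.DataFrame.from_records(records)
    rows = [r for c in centers for r in _summaries(estimates, specs, c, n_reps, seed)]
    return _results_frame(rows), estimates


def run_asymptotic_benchmark(
    sample_sizes: list[int] = (50, 100, 200, 400),
    n_reps: int = 300,
    truth: float = 1.0,
    model: SinusoidModelParams | None = None,
    nw: float = 2.0,
    n_tapers: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Distribution summaries of pre (k = 3) and post (k = n/2) across sizes.

    Returns one row per (estimator, sample size) with mean, bias, variance
    and the 5th/95th percentiles of the ``n_reps`` estimates.
    """
    sizes = list(sample_sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sample_sizes must be strictly increasing")
    if sizes[0] <= 4:
        raise ValueError("smallest sample size is too small for k-NN estimation")
    if model is None:
        model = SinusoidModelParams()
    model = replace(model, sigma_b=sigma_b_for_true_mif(truth))
    bin_f0 = frequency_to_bin(model.f0, model.n_samples, model.fs)
    tapers = generate_dpss(model.n_samples, nw=nw, n_tapers=n_tapers)
    cfg_pre = EstimatorConfig(method="knn", k_rule="fixed", k_fixed=3)
    cfg_post = EstimatorConfig(method="knn", k_rule="half_samples")

    ss = np.random.SeedSequence(seed)
    rows = []
    for n in sizes:
        m = replace(model, n_paths=n)
        ests = {"pre": np.empty(n_reps), "post": np.empty(n_reps)}
        for rep, s in enumerate(ss.spawn(n_reps)):
            rng = np.random.default_rng(s)
            x, y = simulate_random_sinusoids(m, rng=rng)
            dx = increment_matrix(x, tapers, bins=[bin_f0])[:, :, 0]
            dy = increment_matrix(y, tapers, bins=[bin_f0])[:, :, 0]
            ests["pre"][rep] = _mif_from_increments(dx, dy, cfg_pre, "pre")
            ests["post"][rep] = _mif_from_increments(dx, dy, cfg_post, "post")
        for label, e in ests.items():
            rows.append(
                dict(
                    estimator=label,
                    n_paths=n,
                    truth=truth,
                    mean=float(e.mean()),
                    bias=float(e.mean() - truth),
                    variance=float(e.var()),
                    p5=float(np.percentile(e, 5)),
                    p95=float(np.percentile(e, 95)),
                    n_reps=n_reps,
                    seed=seed,
                )
            )
    return pd.DataFrame(rows)
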