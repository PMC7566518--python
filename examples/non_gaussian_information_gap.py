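"""Coherence misses information on a non-Gaussian process; MIF does not.

Switching the sinusoid amplitudes from Rayleigh to Uniform(-0.5, 0.5) makes
the model non-Gaussian (marginal kurtosis 2.7 instead of 3) while leaving its
second-order structure — and hence the coherence — unchanged.  The
coherence-to-MIF transform, exact for Gaussian processes, now underestimates
the directly estimated mutual information: the gap is the dependence that
second-order statistics cannot see.
"""

import numpy as np

from mifreq import (
    EstimatorConfig,
    SinusoidModelParams,
    analytic_kurtosis,
    coherence_to_mif,
    estimate_coherence,
    estimate_mif_at,
    generate_dpss,
    simulate_random_sinusoids,
)

cfg = EstimatorConfig(method="knn", k_rule="fixed", k_fixed=3)
tapers = generate_dpss(128, nw=2.0, n_tapers=3)

n_reps = 30
mifs, cohs = np.empty(n_reps), np.empty(n_reps)
for rep in range(n_reps):
    params = SinusoidModelParams(
        n_paths=2000, amplitude_family="uniform", seed=100 + rep
    )
    x, y = simulate_random_sinusoids(params)
    mifs[rep] = estimate_mif_at(x, y, 8.0, 8.0, tapers, cfg, "pre")
    c = estimate_coherence(x, y, tapers, frequencies=[8.0]).coherence[0]
    cohs[rep] = coherence_to_mif(c)

gap = mifs.mean() - cohs.mean()
se = np.sqrt(mifs.var(ddof=1) / n_reps + cohs.var(ddof=1) / n_reps)
print(f"marginal kurtosis (analytic)      : {analytic_kurtosis('uniform'):.2f}  (Gaussian = 3)")
print(f"mean -ln(1 - C(f0))    [nats]     : {cohs.mean():.4f} +- {cohs.std(ddof=1):.4f}")
print(f"mean pre k-NN MIF(f0)  [nats]     : {mifs.mean():.4f} +- {mifs.std(ddof=1):.4f}")
print(f"information gap        [nats]     : {gap:.4f}  ({gap / se:.1f} standard errors)")
print()
print("A positive gap of several standard errors shows the transformed")
print("coherence under-reports the coupling of this non-Gaussian pair.")
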