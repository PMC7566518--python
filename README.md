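# mifreq

Multitaper estimation of **mutual information in frequency (MIF)** and
**coherence** for pairs of trialized time series, with the simulation models,
estimator benchmarks and permutation/bootstrap statistics needed to correlate
frequency coupling with task performance.

## The problem

Neuroscientists routinely summarize the frequency-domain relationship between
two signals — say, two local-field-potential channels in visual cortex —
and then correlate that *frequency coupling* with behaviour (task accuracy,
learning, arousal).  The standard coupling measure is magnitude-squared
coherence,

```
C_XY(f) = |S_XY(f)|^2 / (S_X(f) S_Y(f))  ∈ [0, 1],
```

which captures *all* dependence only when the signals are Gaussian processes.
Neural signals are not Gaussian.  Mutual information in frequency removes the
model assumption: writing each process through its Cramér spectral
representation, the complex Fourier increment `dX̃(f) = [dX̃_R, dX̃_I]` is a
2-vector random variable, and

```
MIF(f_i, f_j) = I( dX̃(f_i) ; dỸ(f_j) )        [nats]
              = h(dX̃) + h(dỸ) − h(dX̃, dỸ),
```

estimated nonparametrically with the Kozachenko–Leonenko k-nearest-neighbour
entropy estimator.  For linear Gaussian processes the two scales are linked
exactly by `MIF(f, f) = −ln(1 − C_XY(f))`, so coherence pipelines can be read
in nats; for non-Gaussian signals the transform *underestimates* the true
information — the gap is what coherence cannot see.

A second concern drives the design: when coupling is correlated with
behaviour, the **variance** of the coupling estimator (not its bias) caps the
measurable correlation.  Multitaper estimation — projecting each trial onto K
orthonormal Slepian (DPSS) tapers — yields K quasi-independent spectral
samples per trial.  The package implements the three ways to fold them into
an MI estimate:

| strategy | recipe |
|----------|--------|
| `naive`  | pool all `n_trials × K` increment samples, estimate once |
| `pre`    | average samples across tapers in the complex plane per trial, estimate once |
| `post`   | estimate per taper, average the K estimates |

together with benchmarks (on a random-sinusoid model with closed-form truth
`MIF = ln(1 + 1/σ_B²)`) showing that pooled (naive) estimation inflates
variance and degrades truth-correlation, while `post`/`pre` with the
half-the-samples neighbour rule keep variance low.

## Worked example

```bash
python examples/coherence_vs_mif_gaussian.py
```

```
coherence at f0                : 0.5131   (theory 1/(1+sigma_b^2) = 0.5)
-ln(1 - C)  [nats]             : 0.7197
pre k-NN MIF(f0, f0)  [nats]   : 0.7570
closed-form truth     [nats]   : 0.6931  (= ln 2)
```

2000 trials of the Gaussian sinusoid pair `Y = X + W` with `σ_B = 1` give a
coherence of ≈ 0.5 at the oscillation frequency; its transform to nats and
the direct pre-averaged k-NN MIF estimate both land near the closed-form
truth ln 2 (the k-NN estimator carries a small positive bias at this sample
size).  The other examples show the non-Gaussian information gap
(`non_gaussian_information_gap.py`), the estimator-comparison benchmark
(`estimator_benchmark.py`) and the full sliding-window coupling-vs-accuracy
pipeline with permutation gating and block-bootstrap confidence intervals
(`task_session_analysis.py`).

A thin CLI exposes the same pipelines
(`mifreq simulate|coherence|mif|benchmark|sigtest|taskcorr`); trial matrices
are plain delimited text with a `# fs=<Hz> t0=<s>` header.

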