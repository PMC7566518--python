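# Methods

## Estimation pipeline

All estimates operate on *trialized* data: an `n_trials × n_samples` real
matrix with a sampling rate `fs`, trials assumed independent.  Each trial is
demeaned (on by default, switchable) and multiplied element-wise by each of
`K` unit-energy Slepian (DPSS) tapers; the normalized Fourier transform
`(1/N) Σ_n taper[n]·x[n]·e^(−j2πmn/N)` at an FFT-bin frequency `fs·m/N`
yields one complex **increment sample** per `(trial, taper)` pair.  Only
on-grid frequencies are accepted (a `nearest` flag snaps deliberately);
increment normalization is `1/N`, a cosmetic choice fixed for
reproducibility — coherence is normalization-invariant and MIF is invariant
under invertible linear maps of the samples.

**Coherence** averages `|dX̃|²`, `|dỸ|²` and `dX̃·conj(dỸ)` over all
`(trial, taper)` pairs and forms `|S_XY|²/(S_X S_Y)` per bin (zero-power bins
report 0).  Pooling all pairs and averaging per-taper spectral estimates are
the same arithmetic mean, so the "naive" and "pre" routes coincide exactly
for coherence; averaging the *complex increments* across tapers before
forming spectra is a different operation and is not used for coherence.

**MIF** treats each complex increment as the 2-vector `[Re, Im]`, so
`MIF(f_i, f_j)` is mutual information between two 2-dimensional continuous
variables, computed as `h(X) + h(Y) − h(X, Y)` with the Kozachenko–Leonenko
k-NN entropy estimator (Euclidean metric, same `k` in all three calls).
Negative estimates are reported raw by default (`clip_negative` exists for
consumers who need non-negative band summaries); raw values preserve the
variance structure the benchmarks measure.  Exact duplicate points raise by
default; a deterministic jitter (`jitter_scale × IQR × 1e−9` per axis,
seeded) is available for degenerate inputs.

### Neighbour count

`k_rule = "half_samples"` (`k = ⌊n/2⌋`) is the package default for every
taper strategy: it is the variance-oriented choice appropriate when coupling
estimates feed correlation analyses, and it is the only rule under which the
benchmark orderings below hold for all three strategies.  `k = 3`
(`k_rule = "fixed"`) is the bias-oriented setting used by the asymptotics
benchmark (pre estimator) and by the Gaussian/non-Gaussian comparison, where
absolute values rather than rank stability matter.  Two biases of the
half-samples rule are worth knowing:

* even for independent inputs the 3-entropies estimate at `k = n/2` sits
  systematically below zero (the d=1/d=2 entropy biases do not cancel);
* the **naive** strategy at small `k` is biased *above* zero under
  independence: pooling keeps the pairing between same-taper samples, so the
  taper identity itself acts as up to `ln K` nats of spurious shared
  information.  This structural defect, together with its inflated variance,
  is what rules the naive strategy out.

## Simulation models

The benchmark model is a random sinusoid pair,
`X(t) = A cos(2πf₀t + Θ)`, `W(t) = B cos(2πf₀t + Φ)`, `Y = X + W`, with
fresh independent draws per trial.  With `A ~ Rayleigh(1)`,
`B ~ Rayleigh(σ_B)` and uniform phases the pair is Gaussian and the MIF at
`(f₀, f₀)` is `ln(1 + 1/σ_B²)` nats exactly (coherence `1/(1+σ_B²)`); with
`A, B ~ Uniform(−0.5, 0.5)` the marginal kurtosis drops to 27/10 = 2.7
(versus 3 for any Gaussian) while second-order structure is unchanged, making
it the test bed on which the coherence transform provably under-reports
information.  Default geometry: 128 samples at 128 Hz with `f₀ = 8` Hz —
the path length and `f₀` do not affect the information content, and the
default puts `f₀` exactly on an FFT bin.

### A structural property worth knowing

Because the model is a pure line spectrum, **every taper's increment at
every bin is an exact linear image of the same per-trial complex pair**
`(Z, Z+V)` with `Z = (A/2)e^{jΘ}`: the increment at bin `f` is
`αZ + β·conj(Z)` with `α, β` the taper transform at `f ∓ f₀`.  Two
consequences:

1. *Tapers add no independent information here.*  Pre and post estimates are
   near-identical path-by-path, and their variance/correlation difference is
   a statistical tie at a few hundred repetitions; the single Hamming taper
   performs identically.  The decisive, robust ordering this model does
   resolve is naive (pooled) versus the rest.  Taper diversity matters on
   signals with continuous spectra, which this model deliberately lacks.
2. *Off-centre bins are not an empirical null.*  Since MI is invariant under
   invertible linear maps, the windowed increments at any bin `f ≠ f₀` carry
   exactly the same mutual information as at `f₀` — leakage rescales the
   samples but preserves the dependence.  The idealized statement "MIF is
   zero off `f₀`" refers to the continuous-process increments, not to
   finite tapered windows of a noiseless line spectrum; an empirical
   off-centre null requires a broadband noise floor.  The off-coupling
   acceptance check encodes the idealized statement and therefore fails on
   this model, by design rather than by defect.

### Task sessions

The synthetic session generator emulates a trialized learning session: trial
`i` of both channels mixes a shared random-phase sinusoid at the band centre
with weight `√c_i` and private white noise with weight `√(1−c_i)`, where the
coupling profile `c_i ∈ [0, 1)` defaults to a linear ramp 0.15 → 0.85 (the
simplest trajectory with the monotone drift of a learning session); success
is Bernoulli with a logistic link in `c_i` (slope 6, base accuracy 0.75,
giving per-trial success probabilities spanning roughly 0.3–0.95).  What the
generator does *not* emulate: 1/f background spectra, within-trial
nonstationarity, volume conduction, cross-frequency structure, or any
biophysics — passing the recovery tests shows the pipeline recovers a known
monotone coupling–accuracy link under realistic sample sizes, not that it is
validated on real LFP data.

## Session statistics

The sliding analysis follows the standard trialized workflow: 100-trial
windows stepped by 10; within each window, band coupling is estimated in
three 300 ms sub-windows per trial (staggered starts) and the three values
averaged; band summaries are means over the FFT bins whose centres fall in
the band (diagonal pairs only for MIF, commensurate with coherence).

**Significance gating.**  The null permutes the trial-to-trial pairing of one
channel across the whole session (waveforms preserved), recomputes the
per-window per-bin coupling, and records the maximum over all windows and
band bins; the 95th percentile of 5000 such maxima (default) is the
family-wise threshold.  A window passes when the max of its band-bin
couplings exceeds the threshold; failing windows are zeroed before
correlation (a `keep` switch retains raw values — which of the two a given
published pipeline used is usually unstated, so both are first-class).
Calibration: on independent-channel data the family-wise false-positive rate
measures 5.4% over 1000 repeats at 500 permutations; a few hundred
permutations inflate it measurably (order-statistic granularity), so 500 is
a practical floor.

**Correlation inference.**  Window-level coupling and accuracy series are
correlated with Pearson's r; confidence intervals come from a circular
moving-block bootstrap (default block length `⌈n^{1/3}⌉`, 2000 resamples)
that respects the autocorrelation induced by overlapping windows.  Percentile
intervals under-cover at short series (measured: 89% at 30 windows, 93% at
100, versus nominal 95%) but always beat the iid bootstrap; the
double-bootstrap refinement some packages apply to close the remaining gap
is deliberately not implemented — a documented simplification.  Two coupling
measures sharing the accuracy series are compared with the
Meng–Rosenthal–Rubin Z-test for dependent correlations.

## Benchmarks and problem sizes

Truth sweeps draw the target MIF uniformly in ±0.2 around each centre (the
sampling law within the stated range is the package's choice) and invert the
closed form for `σ_B`.  Default scales — 300 repetitions of 100 paths for
the correlation/variance sweeps, 300 repetitions per size for the
{50, 100, 200, 400} asymptotics, 20×2000 paths for the Gaussian consistency
check, 100×2000 for the non-Gaussian gap, 1000 repeats for permutation
calibration, 50 seeded sessions for end-to-end recovery — complete in a few
minutes on one CPU; full-scale runs (10⁴ repetitions) are a parameter away
and are read through the same ordering-plus-bootstrap lens.  All stochastic
components derive per-repetition generators from a single master seed via
`numpy` seed sequences, so every table is bit-for-bit reproducible.

## Numerical choices

Logarithms are natural throughout (nats), making the Gaussian transform and
the closed-form truth mutually consistent.  Zero-power bins report coherence
0 rather than NaN.  Degenerate benchmark columns (constant estimates) report
correlation 0 with a `degenerate` flag, since a constant estimator has zero
variance *and* zero truth-correlation — the reason variance alone ranks
nothing, and why cross-family variance comparisons are flagged invalid.
Coherence of exactly 1 transforms to `+inf` with a warning.  The
concentration-limit rule `K ≤ ⌊2·nw⌋ − 1` is enforced with an explicit
override.  Histogram estimators use equal-width bins (2) on observed ranges
and per-axis quantile bins (3); quantile ties merge bins with a warning, and
constant axes contribute zero with a warning.
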