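# Methods

## Model and procedure

Given a uniformly sampled series `x(t)`, `t = 1..T`, the cumulative
profile is `y(t) = Σ_{t'≤t}(x(t') − mean(x))`.  Subtracting the mean is
essential here (not merely conventional): it zeroes the DC Fourier
coefficient and the profile's endpoint, which is what makes the periodic
boundary conditions of the spectral formulation harmless.

**Classical route.** `y` is tiled from the start into `K = floor(T/L)`
disjoint segments of length `L` (the trailing remainder is discarded; no
second pass from the end).  Each segment is detrended by an ordinary
least-squares line and `F²(L) = (1/KL) Σ z²`.  The per-position
diagnostic `G²(L, t) = (1/K) Σ_k z_k²(t)` shows the built-in
non-stationarity: `G` has maxima at the segment edges and center and
minima near `L(1 ∓ 1/√3)/2`, following the absolute value of the
residual quadratic `a((t − L/2)² − (L/2)²/3)` — samples are treated
differently purely by their position inside an arbitrary tiling.

**Stationary route.** Every sample is the center of its own segment;
detrending at the center reduces to subtracting the segment mean of the
profile, i.e. a circular convolution with a boxcar.  In the Fourier
domain,

    F²(L) = (1/T²) Σ_{f=1..⌊T/2⌋} m(f) · w(f, L) · P(f) / (4 sin²(πf/T)),

where `P(f) = |x̂(f)|²` is the one-sided power of the mean-subtracted
data, `m(f) = 2` for paired bins and `1` for the unpaired Nyquist bin of
an even-length record (summing past Nyquist would double-count), and
`4 sin²(πf/T)` is the exact discrete transfer of the cumulative sum.
The slope `d log F/d log L` is computed from the window's exact
analytic scale derivative `∂w/∂L`; it is a weighted average of
per-frequency local exponents and therefore bounded by their extremes.

## Windows

| family  | scale | weight `w(f)` | scale derivative |
|---------|-------|----------------|------------------|
| boxcar  | width `L` (real > 0) | `(1 − sin(πfL/T)/(L sin(πf/T)))²` | chain rule of the closed form |
| gaussian| `σ` in samples | `(1 − e^(−2π²(f/T)²σ²))²` | `−2(1−ĥ)·∂ĥ/∂σ` |
| kiyono0/1 | width `L` | phase-averaged order-0/1 segment-detrending weight | closed-form derivative |
| custom  | user | any `w(f, scale, T) ≥ 0`, `w(0) = 0` | analytic if supplied, else centered FD |

Conventions and numerical choices:

* Scales are in **samples** internally; the CLI accepts seconds and
  converts by `fs`.  Public scale arguments are *equivalent boxcar
  widths*: the Gaussian is evaluated at `σ = L/√12` (equal standard
  deviation), under which `d log σ = d log L`, so slopes are
  unaffected.
* `f = 0` takes explicit limit values (transfer 1, weight 0) rather than
  evaluating the singular formula; mean subtraction makes that bin
  irrelevant anyway.
* The printed closed forms of the order-0/1 phase-averaged weights are
  defined up to global constants (they tend to `2π²` and `2π⁴` at high
  frequency).  We normalize both by those limits so every family's
  weight tends to 1, which makes fluctuation amplitudes comparable
  across families and the weight→kernel inversion well behaved; slopes
  are invariant to the constant.  Both weights were validated against a
  numerical phase-average oracle (order-n detrended unit oscillations
  averaged over segment phase), which fixes the order-1 transcription
  unambiguously.
* The order-1 weight suffers catastrophic float64 cancellation for
  `u = fL/T ≲ 0.1` (its leading behavior is `(2π)⁸u⁴/5760` after terms
  through `u⁶` cancel).  Small arguments use a three-term Taylor series
  (`u < 0.03`); the direct form is evaluated in 80-bit extended
  precision.  The boxcar slope weight printed in the literature is
  dimensionally inconsistent (a missing `1/T`); we differentiate the
  transfer function symbolically and verify every family against a
  centered finite-difference oracle at `1e−5`.
* Normalization of the spectral sum is fixed at `1/T²`, the unique
  constant for which the Fourier route reproduces the time-domain
  moving-average detrending *exactly* (verified to ~1e−16 relative);
  the constant is identical across families.
* The time-domain kernel of any non-negative weight is recovered as the
  inverse DFT of `h̃ = 1 − √w` (tiny negative rounding residues are
  clipped before the root).  The order-0 kernel decays steadily out to
  twice the segment length and slowly beyond; the order-1 kernel
  resembles the Gaussian but dips slightly negative.
* Slopes at `L < 3` samples or `L > T/2` are computed but flagged
  untrusted (`trusted_`/`trusted` columns): the discrete window barely
  spans a sample below, and periodicity dominates above.
* Default scale grid: 130 log-spaced scales between 10 ms and 200 s,
  clamped to `[3 samples, T/4]`.

## Synthetic data

The generators emulate the classes of signal the method is validated
on, with defaults matching those study conditions:

* **colored_noise(γ)** — spectral synthesis (unit-variance complex
  Gaussian coefficients scaled by `f^(−γ/2)`), giving an exactly
  controlled power law; valid for `−1 < γ < 3`; standardized output.
  Spectral synthesis (rather than AR filtering) was chosen precisely so
  the expected slope `(1+γ)/2` is exact, not asymptotic.
* **weierstrass_series(D)** — `Σ_k b^(−k(2−D)) cos(2π b^k t/n + φ_k)`
  with base `b = 1.5`, zero phases by default, components up to the
  Nyquist index.  Component spacing makes the graph self-similar only
  under discrete rescaling, so the local slope oscillates with period
  `log b` in `log L` around `H = 3 − D`; any base in (1.1, 2] shows the
  effect, and `b` controls its period.
* **roessler_series** — `dx/dt = −y − z, dy/dt = x + ay,
  dz/dt = b + z(x − c)` at the classic chaotic set
  `(a, b, c) = (0.2, 0.2, 5.7)`, integrated with an adaptive 8th-order
  Runge–Kutta scheme (rtol 1e−8), 100 model-time units of transient
  discarded, time linearly rescaled so the dominant spectral peak of
  `x` (estimated on a pilot integration) lands at the target ~10 Hz,
  then sampled at `fs`.  The alternative set (0.15, 0.2, 10) was tried
  and yields envelope slopes of ~0.35–0.42 at 5–30 s instead of the
  expected decay to ~0.5; the classic set reproduces it, which is why
  it is the default.  The seed only jitters the initial condition.
* **filtered_noise_envelope** — white Gaussian noise through a
  linear-phase FIR bandpass (Hamming window design, odd length
  ≈ `fir_seconds·fs`, applied without net delay), then the
  analytic-signal magnitude.  Only the filter length and band are
  prescribed by the use case; the window-method design is our choice
  and is swappable.

What the simulations do *not* emulate: source mixing and
volume-conduction effects of real EEG/MEG recordings, measurement
noise floors, non-stationary amplitude regimes, or finite-precision
acquisition.  Passing tests therefore demonstrate the estimator's
correctness and stability on signals with *known* scaling, not that any
particular empirical record has a given Hurst exponent.

## Envelope statistics

Band envelopes use the same zero-delay FIR bandpass followed by the
Hilbert-transform magnitude; output length equals input length, and
samples within half a filter length of the edges are attenuated by the
truncated convolution.  Spectral-peak SNR is computed on a Welch
spectrum with 1-s segments (exactly 1 Hz resolution) as
`(P(f) − N(f))/N(f)` with `N(f)` the mean of the powers at `f ± 2` Hz;
the selection threshold (default 5) is a configurable convention, not a
derived quantity.  For means over correlated observations the standard
error is inflated by `λ = √(1 + (N−1)ρ̄)`, with `ρ̄` the mean
off-diagonal correlation — envelope correlations serve as the proxy
when the correlation of derived quantities is unknown.

## Problem sizes and determinism

Validation experiments use 10-minute records at 256 Hz for pink noise
(10 realizations), `n = 2¹⁷` samples for slope-recovery checks,
300 000 points for the fractal series, 27 minutes at 100 Hz for the
chaotic oscillator, and 10–15 minutes at 300 Hz for filtered-noise
envelopes — the sizes at which the reproduced behaviors were
established.  Every stochastic step is driven by
`numpy.random.default_rng` seeds derived from a single master seed via
`SeedSequence`; identical configurations are bit-identical.

## Known limitations

* Classical DFA is linear-detrend only; higher polynomial orders and
  multifractal extensions are out of scope, as are order ≥ 2
  phase-averaged kernels.
* The stationary route assumes periodicity; with mean subtraction the
  bias is negligible for `L ≪ T` (no systematic inflation measured up
  to `L = T/10`), but slopes beyond `T/2` are untrustworthy by
  construction.
* Confidence intervals for single-series slopes are deliberately not
  provided: long-range correlation undermines the independence
  assumptions such intervals would need.
* The validity range of `γ` for which the power-law slope law holds is
  taken as `(−1, 3)`; outside it the implementation warns rather than
  fails, since the divergence depends on the window family.
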