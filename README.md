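# stationary-dfa

Stationary detrended fluctuation analysis (DFA) in the Fourier domain,
with **analytic local slopes** — for estimating long-range temporal
correlations (Hurst exponents) in uniformly sampled biological time
series, in particular amplitude envelopes of neural oscillations
(EEG/MEG alpha rhythm and the like).

## Why

Classical DFA divides the cumulative profile `y(t) = Σ (x(t') − c)` into
disjoint segments of length `L`, removes a least-squares line per
segment and studies the residual RMS `F(L)`.  That procedure is
*methodologically non-stationary*: a sample near a segment edge is
detrended differently from one in the middle, although the data warrant
no such distinction.  The practical cost is that `F(L)` fluctuates so
strongly under small changes of `L` that the local slope
`d log F / d log L` — the quantity of scientific interest — can only be
obtained by fitting a line over a wide scale range, presupposing the
very scaling law one wants to test.

The remedy is to give every sample its own centered segment, where
linear detrending reduces to subtracting a centered moving average of
the profile (the detrending-moving-average construction):

    z(t) = y(t) − (1/L) Σ_{|τ| ≤ (L−1)/2} y(t+τ),   F²(L) = (1/T) Σ_t z²(t)

This is stationary, and by Parseval and the convolution theorem it is a
weighted average over the one-sided power spectrum,

    F²(L) = (1/T²) Σ_{0<f≤T/2} m(f) · w(f, L) · |x̂(f)|² / (4 sin²(πf/T)),

with `w(f, L) = (1 − ĥ_L(f))²` the spectral weight of the detrending
window (boxcar: `ĥ_L(f) = sin(πfL/T)/(L sin(πf/T))`) and `m(f)` the
conjugate-pair multiplicity.  In this form `L` is a free *real*
parameter and the local slope is an exact derivative,

    d log F / d log L = [Σ m(f) · L ∂w/∂L · |x̂|²/(4 sin²)] / (2 T² F²),

a statistically robust weighted average of per-frequency exponents.  For
a power-law spectrum `⟨|x̂(f)|²⟩ ∝ f^(−γ)` the slope is `(1+γ)/2`:
0.5 for white noise, 1 for pink noise.

Supported detrending windows: **boxcar**, **Gaussian**
(`σ = L/√12`, matched standard deviation), the phase-averaged order-0/1
segment-detrending kernels (**kiyono0**/**kiyono1**), and arbitrary
user-supplied non-negative spectral weights, each with exact scale
derivatives and an inverse map back to its time-domain kernel.

## Worked example

```python
import numpy as np
from stationary_dfa import SpectralDFA, colored_noise

fs = 256.0
x = colored_noise(1.0, int(600 * fs), fs=fs, seed=7)   # 10 min of pink noise

est = SpectralDFA(window="boxcar", fs=fs, n_scales=40).fit(x)
mid = est.trusted_ & (est.scales_seconds_ > 0.1) & (est.scales_seconds_ < 10)
print(f"mean local slope (0.1-10 s): {est.slope_[0, mid].mean():.3f}")
```

prints

```
mean local slope (0.1-10 s): 0.992
```

— the Hurst exponent of pink noise is 1, and the analytic slope recovers
it locally, scale by scale, without any line fitting.  The fitted
estimator exposes `scales_`, `fluctuation_` (`F` per series and scale),
`slope_` and `trusted_`; `ClassicalDFA` provides the segment-wise
reference route.  Estimators follow the scikit-learn transformer
contract and compose with pipelines; `transform(X)` returns the slope
features of new series on the fitted scale grid.

The same functionality is scriptable:

```bash
sdfa simulate --kind colored_noise --n 153600 --fs 256 --seed 7 \
     --param gamma=1.0 --out pink.csv
sdfa fluct pink.csv --fs 256 --method fourier --window boxcar --out-dir results/
sdfa slope pink.csv --fs 256 --window gaussian --out-dir results/
sdfa experiment method-agreement --seed 0
```

plus `envelope` (band-limited Hilbert amplitudes), `snr` (spectral-peak
signal-to-noise, the oscillation-selection criterion) and further
`experiment` presets (`paired-scales`, `fractal`, `chaotic-envelope`,
`filtered-envelopes`, `two-intervals`).

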