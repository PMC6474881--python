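"""Local slopes d log F / d log L, analytic and finite-difference.

The central payoff of the stationary Fourier formulation: the local
slope of the fluctuation function is an exact derivative, not a fit.
With F^2(L) = sum_f m(f) w(f, L) P(f) / (4 sin^2(pi f/T)) / T^2 and the
window's exact scale derivative dw/dL,

    d log F / d log L = [sum_f m(f) L dw/dL P(f) / (4 sin^2)] / (2 T^2 F^2)

which is a statistically robust weighted average across the power
spectrum: each frequency contributes its own local exponent, weighted by
its share of F^2.  For a power-law spectrum <|x^(f)|^2> ~ f^-gamma the
slope is (1 + gamma)/2, e.g. 1/2 for white noise and 1 for pink noise.

Scales are expressed as equivalent boxcar widths L in samples
throughout; the Gaussian window is evaluated at sigma = L/sqrt(12), for
which d log L = d log sigma so the slope is unchanged by the
reparameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluctuation import (
    FluctuationCurve,
    SpectrumHalf,
    _resolve_window,
    _weighted_sum,
    classical_dfa,
    spectrum_half,
)

__all__ = [
    "SlopeCurve",
    "fourier_slope",
    "slope_curve",
    "finite_difference_slope",
    "theoretical_powerlaw_slope",
    "two_interval_slopes",
    "trust_mask",
]

#: slopes at scales below this many samples are flagged untrusted
MIN_TRUSTED_SAMPLES = 3.0


@dataclass(frozen=True)
class SlopeCurve:
    """Local slope d log F / d log L over a scale grid (samples)."""

    scales: np.ndarray
    slope: np.ndarray
    window: str = "n/a"
    fs: float = 1.0
    trusted: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scales.shape != self.slope.shape:
            raise ValueError("scales and slope must have matching shapes")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def scales_seconds(self) -> np.ndarray:
        return self.scales / self.fs

    def to_frame(self, channel: str = "0") -> pd.DataFrame:
        trusted = self.trusted if self.trusted is not None else np.ones(self.scales.shape, bool)
        return pd.DataFrame(
            {
                "window": self.window,
                "channel": channel,
                "scale_samples": self.scales,
                "scale_seconds": self.scales_seconds,
                "slope": self.slope,
                "trusted": trusted,
            }
        )


def trust_mask(scales_samples: np.ndarray, T: int) -> np.ndarray:
    """Flag scales outside the trustworthy region [3 samples, T/2].

    Below ~3 samples the discrete window barely spans a point; above
    ~T/2 the periodicity assumption dominates the estimate.
    """
    s = np.asarray(scales_samples, dtype=float)
    return (s >= MIN_TRUSTED_SAMPLES) & (s <= T / 2.0)


def fourier_slope(spec: SpectrumHalf, scale: float, window) -> float:
    """Analytic local slope at a (real) scale from the one-sided spectrum.

    ``window`` is a family name or a WindowTransfer; ``scale`` is the
    equivalent boxcar width in samples.  Raises if F(scale) = 0 (the
    slope is undefined for an empty spectrum).
    """
    win = _resolve_window(window, scale)
    T = spec.T
    f = np.arange(T // 2 + 1)
    F2 = _weighted_sum(spec, np.asarray(win.weight(f, T), dtype=float))
    if F2 <= 0.0:
        raise ValueError("slope undefined: fluctuation vanishes at this scale")
    dw = np.asarray(win.dweight_dscale(f, T), dtype=float) * win.scale
    return _weighted_sum(spec, dw) / (2.0 * F2)


def slope_curve(x_or_spec, scales, window: str = "boxcar", fs: float = 1.0) -> SlopeCurve:
    """Analytic slope over a scale grid (samples) for a series or spectrum."""
    if isinstance(x_or_spec, SpectrumHalf):
        spec = x_or_spec
        fs = spec.fs
    else:
        spec = spectrum_half(x_or_spec, fs=fs)
    scales = np.asarray(scales, dtype=float)
    sl = np.array([fourier_slope(spec, s, window) for s in scales])
    return SlopeCurve(scales=scales, slope=sl,
                      window=window if isinstance(window, str) else window.family,
                      fs=fs, trusted=trust_mask(scales, spec.T))


def finite_difference_slope(curve: FluctuationCurve) -> SlopeCurve:
    """Numerical slope of log F vs log scale (centered differences
    inside, one-sided at the ends).  Validation utility and the only
    slope available to the classical route."""
    if curve.scales.size < 2:
        raise ValueError("need at least 2 scales for finite differences")
    if np.any(curve.F <= 0):
        raise ValueError("finite-difference slope requires F > 0 everywhere")
    sl = np.gradient(np.log(curve.F), np.log(curve.scales))
    return SlopeCurve(scales=curve.scales, slope=sl, window=curve.window, fs=curve.fs)


def theoretical_powerlaw_slope(gamma: float) -> float:
    """Expected slope (1 + gamma)/2 for a power-law spectrum f^-gamma.

    Outside gamma in (-1, 3) the integral constant relating fluctuation
    and scale need not exist for smooth windows; a warning (not an
    error) is emitted.
    """
    if not -1.0 < gamma < 3.0:
        warnings.warn(
            f"gamma={gamma} outside (-1, 3): the power-law fluctuation "
            "integral may not converge for this window class",
            stacklevel=2,
        )
    return (1.0 + gamma) / 2.0


def two_interval_slopes(x, fs: float, interval1: tuple[float, float] = (0.75, 7.5),
                        interval2: tuple[float, float] = (7.5, 75.0),
                        n_scales: int = 100) -> tuple[float, float]:
    """Classical-DFA line-fit slopes over two scale intervals (seconds).

    A log-spaced grid of ``n_scales`` scales spans both intervals; log F
    vs log L is fit by least squares separately in each.  Equal slopes
    indicate a single scaling regime; for narrow-band amplitude
    envelopes the small-scale interval comes out systematically steeper.
    """
    lo1, hi1 = interval1
    lo2, hi2 = interval2
    if not (lo1 < hi1 <= lo2 < hi2):
        raise ValueError("intervals must be increasing and non-overlapping")
    x = np.asarray(x, dtype=float)
    grid_s = np.geomspace(lo1, hi2, n_scales)
    scales = np.unique(np.clip(np.round(grid_s * fs).astype(int), 4, x.size))
    curve = classical_dfa(x, scales, fs=fs)

    def _fit(lo: float, hi: float) -> float:
        sel = (curve.scales_seconds >= lo) & (curve.scales_seconds <= hi)
        if sel.sum() < 3:
            raise ValueError(f"interval ({lo}, {hi}) s contains fewer than 3 scales")
        return float(np.polyfit(np.log(curve.scales[sel]), np.log(curve.F[sel]), 1)[0])

    return _fit(lo1, hi1), _fit(lo2, hi2)
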