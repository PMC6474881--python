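"""Fluctuation functions: classical DFA, stationary DMA, and the Fourier route.

Three routes to the fluctuation function F(L) of a time series x(t):

``classical_dfa``
    Divide the cumulative profile into disjoint segments of length L,
    remove a least-squares line per segment, take the RMS of the
    residuals.  Simple, but methodologically non-stationary: a sample's
    detrending depends on its position inside an arbitrarily placed
    segment, which makes local (finite-difference) slopes of log F
    unusable.

``dma_fluctuation``
    Stationary variant (equivalent to detrending moving average): every
    sample sits at the center of its own segment, where linear
    detrending reduces to subtracting a centered moving average of the
    profile.  Periodic boundary conditions.

``fourier_fluctuation``
    The same stationary quantity computed as a weighted sum over the
    one-sided power spectrum: with spectral weight w(f) of the chosen
    detrending window,

        F^2(L) = (1/T^2) * sum_f m(f) w(f) |x^(f)|^2 / (4 sin^2(pi f/T))

    where m(f) = 2 for 0 < f < T/2 and 1 for the unpaired Nyquist bin of
    an even-length record.  For the boxcar window at odd integer L this
    reproduces ``dma_fluctuation`` exactly (Parseval + convolution
    theorem); the scale is then a free *real* parameter and analytic
    derivatives in the scale become available (see
    :mod:`stationary_dfa.slopes`).

The normalization 1/T^2 is fixed so the Fourier route equals the
time-domain RMS, and is identical across window families so that curves
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .windows import WindowTransfer, equivalent_scale, make_window

__all__ = [
    "SpectrumHalf",
    "FluctuationCurve",
    "SegmentProfile",
    "cumulative_profile",
    "spectrum_half",
    "classical_dfa",
    "segment_profile",
    "dma_fluctuation",
    "fourier_fluctuation",
    "fluctuation_curve",
    "default_scale_grid",
]

METHODS = ("classical", "dma_time", "fourier")


def _validate_series(x, min_len: int = 4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    if x.size < min_len:
        raise ValueError(f"series too short: {x.size} < {min_len}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


@dataclass(frozen=True)
class SpectrumHalf:
    """One-sided power spectrum |x^(f)|^2, f = 0..floor(T/2), DC bin zero."""

    power: np.ndarray
    T: int
    fs: float = 1.0

    def __post_init__(self) -> None:
        if self.power.shape != (self.T // 2 + 1,):
            raise ValueError("power must have floor(T/2)+1 one-sided values")

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.arange(self.T // 2 + 1) * (self.fs / self.T)


@dataclass(frozen=True)
class FluctuationCurve:
    """Fluctuation F over a grid of scales (samples), with method metadata."""

    scales: np.ndarray  # samples, strictly increasing
    F: np.ndarray
    method: str
    window: str = "n/a"
    fs: float = 1.0

    def __post_init__(self) -> None:
        if self.scales.shape != self.F.shape:
            raise ValueError("scales and F must have matching shapes")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    @property
    def scales_seconds(self) -> np.ndarray:
        return self.scales / self.fs

    def to_frame(self, channel: str = "0") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "window": self.window,
                "channel": channel,
                "scale_samples": self.scales,
                "scale_seconds": self.scales_seconds,
                "F": self.F,
            }
        )


@dataclass(frozen=True)
class SegmentProfile:
    """Per-position RMS fluctuation G(L, t) within segments of length L."""

    L: int
    G: np.ndarray

    def __post_init__(self) -> None:
        if self.G.shape != (self.L,):
            raise ValueError("G must have exactly L values")


def cumulative_profile(x) -> np.ndarray:
    """Cumulative sum of the mean-subtracted series.

    The final element is ~0 (up to accumulation rounding) because the
    mean is removed first; this also zeroes the DC Fourier coefficient
    and keeps periodic boundary conditions harmless downstream.
    """
    x = _validate_series(x, min_len=2)
    return np.cumsum(x - x.mean())


def spectrum_half(x, fs: float = 1.0) -> SpectrumHalf:
    """One-sided power spectrum of the mean-subtracted series.

    Downstream sums apply a factor 2 to 0 < f < T/2 (conjugate pairs)
    and 1 to the unpaired Nyquist bin of an even-length record; summing
    the full two-sided range instead would double-count.
    """
    x = _validate_series(x)
    p = np.abs(np.fft.rfft(x - x.mean())) ** 2
    p[0] = 0.0
    return SpectrumHalf(power=p, T=x.size, fs=fs)


def _symmetry_factor(T: int) -> np.ndarray:
    """Multiplicity of one-sided bins: 0 at DC, 2 elsewhere, 1 at even-T Nyquist."""
    m = np.full(T // 2 + 1, 2.0)
    m[0] = 0.0
    if T % 2 == 0:
        m[-1] = 1.0
    return m


def _segments(x, L: int) -> np.ndarray:
    """Detrended segments z_k(t) of the cumulative profile, shape (K, L)."""
    x = _validate_series(x)
    L = int(L)
    if L < 4:
        raise ValueError(f"segment length must be >= 4, got {L}")
    K = x.size // L
    if K == 0:
        raise ValueError(f"scale {L} exceeds series length {x.size}")
    y = cumulative_profile(x)
    segs = y[: K * L].reshape(K, L)
    t = np.arange(L, dtype=float)
    A = np.column_stack([np.ones(L), t])
    coef, *_ = np.linalg.lstsq(A, segs.T, rcond=None)
    return segs - (A @ coef).T


def classical_dfa(x, scales, fs: float = 1.0) -> FluctuationCurve:
    """Classical segment-wise DFA with linear detrending.

    Segments tile from the start of the record; the trailing remainder
    is discarded (no second, reversed pass).  F^2(L) = (1/(K L)) sum z^2.
    """
    scales = np.asarray(scales, dtype=int)
    F = np.empty(scales.shape, dtype=float)
    for i, L in enumerate(scales):
        z = _segments(x, L)
        F[i] = np.sqrt(np.mean(z**2))
    return FluctuationCurve(scales=scales.astype(float), F=F, method="classical", fs=fs)


def segment_profile(x, L: int) -> SegmentProfile:
    """Within-segment fluctuation G(L, t): RMS over segments per position.

    The non-stationarity diagnostic of classical DFA: G(L, t) depends
    systematically on the position t inside the segment (edges and
    center are detrended differently), approximately following the
    absolute value of a quadratic a((t - L/2)^2 - (L/2)^2/3).  The mean
    of G^2 over t equals F^2(L) of :func:`classical_dfa` exactly.
    """
    z = _segments(x, int(L))
    if z.shape[0] < 2:
        raise ValueError("segment_profile needs at least 2 segments")
    return SegmentProfile(L=int(L), G=np.sqrt(np.mean(z**2, axis=0)))


def dma_fluctuation(x, L: int, boundary: str = "periodic") -> float:
    """Stationary fluctuation: subtract the centered moving average.

    Every sample is the center of its own length-``L`` segment (L odd),
    where linear detrending reduces to removing the segment mean of the
    cumulative profile:  z(t) = y(t) - (1/L) sum_{|tau| <= M} y(t+tau).

    boundary='periodic' wraps the profile circularly (the Fourier
    route's implicit convention); 'truncate' discards the M
    boundary-affected samples at each end instead.  With the profile
    mean-subtracted the two agree closely for L << T.
    """
    x = _validate_series(x)
    L = int(L)
    if L % 2 == 0:
        raise ValueError("time-domain moving-average detrending requires odd L")
    if not 3 <= L <= x.size:
        raise ValueError(f"L must be in [3, {x.size}], got {L}")
    y = cumulative_profile(x)
    if boundary == "periodic":
        z = y - ndimage.uniform_filter1d(y, size=L, mode="wrap")
    elif boundary == "truncate":
        M = (L - 1) // 2
        ma = signal.fftconvolve(y, np.full(L, 1.0 / L), mode="valid")
        z = y[M : y.size - M] - ma
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    return float(np.sqrt(np.mean(z**2)))


def fourier_fluctuation(spec: SpectrumHalf, scale: float, window) -> float:
    """Fluctuation at (real-valued) ``scale`` from the one-sided spectrum.

    ``window`` is a :class:`~stationary_dfa.windows.WindowTransfer` (its
    own scale is ignored in favor of ``scale``) or a family name.  For
    the Gaussian family ``scale`` is interpreted as an equivalent boxcar
    width L and converted to sigma = L/sqrt(12).
    """
    window = _resolve_window(window, scale)
    f = np.arange(spec.T // 2 + 1)
    w = np.asarray(window.weight(f, spec.T), dtype=float)
    return float(np.sqrt(_weighted_sum(spec, w)))


def _weighted_sum(spec: SpectrumHalf, w: np.ndarray) -> float:
    T = spec.T
    f = np.arange(T // 2 + 1)
    denom = 4.0 * np.sin(np.pi * f / T) ** 2
    denom[0] = 1.0  # DC excluded by the symmetry factor
    m = _symmetry_factor(T)
    return float(np.sum(m * w * spec.power / denom) / T**2)


def _resolve_window(window, scale: float) -> WindowTransfer:
    if isinstance(window, WindowTransfer):
        return window.with_scale(equivalent_scale_like(window, scale))
    if isinstance(window, str):
        return make_window(window, scale, scale_is_boxcar_width=True)
    raise TypeError("window must be a WindowTransfer or a family name")


def equivalent_scale_like(window: WindowTransfer, L: float) -> float:
    """Convert an equivalent boxcar width to the window's own scale."""
    return equivalent_scale(window.family, L)


def fluctuation_curve(x, scales, window: str = "boxcar", fs: float = 1.0,
                      method: str = "fourier") -> FluctuationCurve:
    """Fluctuation function over a scale grid (scales in samples).

    method='fourier' evaluates the spectral sum for any real scales and
    window family; 'dma_time' uses the time-domain moving average
    (scales rounded to odd integers); 'classical' ignores the window.
    """
    scales = np.asarray(scales, dtype=float)
    if method == "classical":
        ints = np.unique(np.round(scales).astype(int))
        ints = ints[ints >= 4]
        if ints.size == 0:
            raise ValueError("no classical-DFA scales >= 4 samples in the grid")
        return classical_dfa(x, ints, fs=fs)
    if method == "dma_time":
        odd = (2 * np.round((scales - 1) / 2) + 1).astype(int)
        F = np.array([dma_fluctuation(x, L) for L in odd])
        return FluctuationCurve(scales=odd.astype(float), F=F, method="dma_time",
                                window="boxcar", fs=fs)
    if method == "fourier":
        spec = spectrum_half(x, fs=fs)
        F = np.array([fourier_fluctuation(spec, s, window) for s in scales])
        return FluctuationCurve(scales=scales, F=F, method="fourier",
                                window=window, fs=fs)
    raise ValueError(f"unknown method {method!r}")


def default_scale_grid(T: int, fs: float = 1.0, n: int = 130,
                       min_seconds: float = 0.01, max_seconds: float = 200.0) -> np.ndarray:
    """Log-spaced scale grid in samples: 130 points, 10 ms - 200 s by
    default, clamped to [3 samples, T/4]."""
    lo = max(min_seconds * fs, 3.0)
    hi = min(max_seconds * fs, T / 4.0)
    if hi <= lo:
        raise ValueError("record too short for any valid scale")
    return np.geomspace(lo, hi, n)
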