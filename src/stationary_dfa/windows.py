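"""Detrending windows as spectral transfer functions.

Stationary DFA detrends the cumulative profile ``y(t)`` by subtracting a
local average, i.e. a convolution ``(h_L * y)(t)`` with a symmetric,
unit-mass window ``h_L``.  By the convolution theorem the detrended
profile has Fourier coefficients ``z^(f) = (1 - h^_L(f)) y^(f)``, so a
window enters the analysis only through its spectral *weight*

    w(f) = (1 - h^_L(f))**2

and, for analytic slopes, through the derivative of that weight with
respect to the scale.  This module implements the weights and their
exact scale derivatives for

* the **boxcar** window (uniform moving average of width ``L`` samples),
* the **Gaussian** window of standard deviation ``sigma`` samples,
* the phase-averaged **order-0 and order-1 segment-detrending kernels**
  (``kiyono0``/``kiyono1``), which stationarize classical constant/linear
  per-segment detrending,
* arbitrary **custom** non-negative spectral weights,

together with the inverse map from a spectral weight back to its
time-domain detrending window.

Conventions
-----------
Frequencies are one-sided integer indices ``f = 0 .. floor(T/2)`` for a
record of ``T`` samples; the physical frequency of index ``f`` is
``f*fs/T`` Hz.  Scales are in samples.  At ``f = 0`` every weight is 0
by the limit convention (mean subtraction removes the DC coefficient
anyway).  A Gaussian of ``sigma = L/sqrt(12)`` matches the standard
deviation of a boxcar of width ``L``; use :func:`equivalent_scale` to
convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "FrequencyGrid",
    "boxcar_transfer",
    "boxcar_transfer_dscale",
    "gaussian_transfer",
    "gaussian_transfer_dscale",
    "kiyono_weight",
    "kiyono_weight_dscale",
    "transfer_to_time_kernel",
    "WindowTransfer",
    "BoxcarWindow",
    "GaussianWindow",
    "KiyonoWindow",
    "CustomWindow",
    "make_window",
    "equivalent_scale",
    "GAUSSIAN_SIGMA_RATIO",
    "WINDOW_FAMILIES",
]

#: ratio sigma/L matching a Gaussian to a boxcar of width L (std of a
#: uniform distribution of width L is L/sqrt(12))
GAUSSIAN_SIGMA_RATIO = 1.0 / np.sqrt(12.0)

WINDOW_FAMILIES = ("boxcar", "gaussian", "kiyono0", "kiyono1", "custom")

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class FrequencyGrid:
    """One-sided integer frequency grid of a length-``T`` record."""

    T: int
    fs: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError(f"T must be >= 2, got {self.T}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def nyquist_index(self) -> int:
        return self.T // 2

    @property
    def frequencies(self) -> np.ndarray:
        """Integer frequency indices 0 .. floor(T/2)."""
        return np.arange(self.nyquist_index + 1)

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.frequencies * (self.fs / self.T)


def _check_freq(f, T: int) -> np.ndarray:
    """Validate one-sided frequency indices and return them as an array."""
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    fa = np.asarray(f, dtype=float)
    if fa.size and (np.any(fa < 0) or np.any(fa > T // 2)):
        raise ValueError(
            f"frequency index outside one-sided grid [0, {T // 2}] (T={T}); "
            "never evaluate transfers above the Nyquist index"
        )
    return fa


def _check_scale(scale: float, name: str = "scale") -> float:
    scale = float(scale)
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"{name} must be a positive real, got {scale}")
    return scale


# ---------------------------------------------------------------------------
# boxcar
# ---------------------------------------------------------------------------

def boxcar_transfer(f, L: float, T: int):
    """Transfer function of the width-``L`` boxcar moving average.

    ``h^_L(f) = sin(pi f L / T) / (L sin(pi f / T))`` with the limit
    value 1 at ``f = 0``.  ``L`` may be any positive real; for odd
    integer ``L`` this is exactly the DFT of the discrete uniform window
    ``1/L`` on ``|tau| <= (L-1)/2``.
    """
    fa = _check_freq(f, T)
    L = _check_scale(L, "L")
    out = np.ones_like(fa)
    nz = fa > 0
    arg = np.pi * fa[nz] / T
    out[nz] = np.sin(arg * L) / (L * np.sin(arg))
    return out if out.ndim else float(out)


def boxcar_transfer_dscale(f, L: float, T: int):
    """Exact derivative of :func:`boxcar_transfer` with respect to ``L``.

    ``d h^/dL = (pi f/T) cos(pi f L/T)/(L sin(pi f/T))
                - sin(pi f L/T)/(L^2 sin(pi f/T))``; zero at ``f = 0``.
    """
    fa = _check_freq(f, T)
    L = _check_scale(L, "L")
    out = np.zeros_like(fa)
    nz = fa > 0
    arg = np.pi * fa[nz] / T
    s = np.sin(arg)
    out[nz] = (arg * np.cos(arg * L)) / (L * s) - np.sin(arg * L) / (L * L * s)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# gaussian
# ---------------------------------------------------------------------------

def gaussian_transfer(f, sigma: float, T: int):
    """Transfer of a Gaussian window: ``exp(-2 pi^2 (f/T)^2 sigma^2)``.

    The continuous-frequency form uses physical frequency; on the
    discrete grid ``f`` is replaced by ``f/T``.  Value in (0, 1], equal
    to 1 at ``f = 0``.
    """
    fa = _check_freq(f, T)
    sigma = _check_scale(sigma, "sigma")
    out = np.exp(-2.0 * np.pi**2 * (fa / T) ** 2 * sigma**2)
    return out if out.ndim else float(out)


def gaussian_transfer_dscale(f, sigma: float, T: int):
    """Exact derivative of :func:`gaussian_transfer` with respect to sigma."""
    fa = _check_freq(f, T)
    sigma = _check_scale(sigma, "sigma")
    u2 = (fa / T) ** 2
    out = -4.0 * np.pi**2 * u2 * sigma * np.exp(-2.0 * np.pi**2 * u2 * sigma**2)
    return out if out.ndim else float(out)


def _gaussian_one_minus_transfer(f, sigma: float, T: int) -> np.ndarray:
    """``1 - exp(-s)`` via expm1, accurate for small arguments."""
    fa = _check_freq(f, T)
    s = 2.0 * np.pi**2 * (fa / T) ** 2 * sigma**2
    return -np.expm1(-s)


# ---------------------------------------------------------------------------
# Kiyono phase-averaged kernels
# ---------------------------------------------------------------------------
#
# h_n(u) is the spectral weight obtained by averaging classical order-n
# per-segment detrending over the segment phase, with u = f L / T.  Both
# h0 and h1 vanish like u^2 resp. u^4 at u -> 0 after near-total
# cancellation of the trigonometric terms, so small arguments use Taylor
# series and h1 is evaluated in extended precision elsewhere (float64
# loses ~8 digits near the series/direct crossover).

_H0_SMALL = 0.05
_H1_SMALL = 0.03


def _h0(v: np.ndarray) -> np.ndarray:
    """Order-0 weight: ``2 pi^2 + (cos(2 pi v) - 1)/v^2``, v = fL/T."""
    v = np.abs(np.asarray(v, dtype=float))
    out = np.empty_like(v)
    a = _TWO_PI
    small = v < _H0_SMALL
    vs = v[small]
    out[small] = (a**4 / 24.0) * vs**2 - (a**6 / 720.0) * vs**4 + (a**8 / 40320.0) * vs**6
    vl = v[~small]
    out[~small] = 2.0 * np.pi**2 + (np.cos(a * vl) - 1.0) / vl**2
    return out


def _h0_dv(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sign = np.sign(v)
    v = np.abs(v)
    out = np.empty_like(v)
    a = _TWO_PI
    small = v < _H0_SMALL
    vs = v[small]
    out[small] = (a**4 / 12.0) * vs - (a**6 / 180.0) * vs**3 + (a**8 / 6720.0) * vs**5
    vl = v[~small]
    out[~small] = -a * np.sin(a * vl) / vl**2 - 2.0 * (np.cos(a * vl) - 1.0) / vl**3
    return sign * out


def _h1(v: np.ndarray) -> np.ndarray:
    """Order-1 weight, v = fL/T.

    ``h1 = (2 pi^4 v^4 - 4 pi^2 v^2 - 3 + (3 - 2 pi^2 v^2) cos(2 pi v)
            + 6 pi v sin(2 pi v)) / v^4``
    """
    v = np.abs(np.asarray(v, dtype=float))
    out = np.empty_like(v)
    a = _TWO_PI
    small = v < _H1_SMALL
    vs = v[small]
    out[small] = (
        (a**8 / 5760.0) * vs**4
        - (a**10 / 201600.0) * vs**6
        + (a**12 / 14515200.0) * vs**8
    )
    vl = v[~small].astype(np.longdouble)
    al = np.longdouble(2.0) * np.longdouble(np.pi)
    N = (
        (al**4 / 8.0) * vl**4
        - al**2 * vl**2
        - 3.0
        + (3.0 - (al**2 / 2.0) * vl**2) * np.cos(al * vl)
        + 3.0 * al * vl * np.sin(al * vl)
    )
    out[~small] = (N / vl**4).astype(float)
    return out


def _h1_dv(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sign = np.sign(v)
    v = np.abs(v)
    out = np.empty_like(v)
    a = _TWO_PI
    small = v < _H1_SMALL
    vs = v[small]
    out[small] = (
        (a**8 / 1440.0) * vs**3
        - (a**10 / 33600.0) * vs**5
        + (a**12 / 1814400.0) * vs**7
    )
    vl = v[~small].astype(np.longdouble)
    al = np.longdouble(2.0) * np.longdouble(np.pi)
    c = np.cos(al * vl)
    s = np.sin(al * vl)
    N = (
        (al**4 / 8.0) * vl**4
        - al**2 * vl**2
        - 3.0
        + (3.0 - (al**2 / 2.0) * vl**2) * c
        + 3.0 * al * vl * s
    )
    Np = (al**4 / 2.0) * vl**3 - 2.0 * al**2 * vl + 2.0 * al**2 * vl * c + (al**3 / 2.0) * vl**2 * s
    out[~small] = (Np / vl**4 - 4.0 * N / vl**5).astype(float)
    return sign * out


#: global constants dividing the raw order-0/1 weights so that, like
#: (1 - h^)^2 of the boxcar/gaussian families, they tend to 1 at high
#: frequency.  The raw weights are defined only up to a constant; this
#: choice makes fluctuation curves comparable across families and equals
#: twice the phase-averaged detrended variance of a unit oscillation.
KIYONO_NORMALIZATION = {0: 2.0 * np.pi**2, 1: 2.0 * np.pi**4}


def kiyono_weight(f, L: float, T: int, order: int, raw: bool = False):
    """Phase-averaged segment-detrending weight ``h_order(f L / T)``.

    ``order=0`` removes a constant per segment, ``order=1`` a linear
    trend; averaging over segment phase makes classical per-segment
    detrending stationary.  The weight is analytically non-negative;
    tiny negative floating residues are clipped to 0.  Returns 0 at
    ``f = 0``.

    By default the weight is divided by ``KIYONO_NORMALIZATION[order]``
    so it tends to 1 at high frequency like the other families;
    ``raw=True`` returns the unnormalized closed form
    ``h0 = (2 pi^2 f^2 L^2 + cos(2 pi f L) - 1) / (f^2 L^2)`` (and its
    order-1 analogue), in which f stands for the ratio (index)/T.
    """
    fa = _check_freq(f, T)
    L = _check_scale(L, "L")
    if order not in (0, 1):
        raise ValueError(f"order must be 0 or 1, got {order!r}")
    v = fa * (L / T)
    h = _h0(v) if order == 0 else _h1(v)
    out = np.maximum(h, 0.0)
    if not raw:
        out = out / KIYONO_NORMALIZATION[order]
    return out if out.ndim else float(out)


def kiyono_weight_dscale(f, L: float, T: int, order: int, raw: bool = False):
    """Exact derivative of :func:`kiyono_weight` with respect to ``L``."""
    fa = _check_freq(f, T)
    L = _check_scale(L, "L")
    if order not in (0, 1):
        raise ValueError(f"order must be 0 or 1, got {order!r}")
    u = fa / T
    v = u * L
    dv = _h0_dv(v) if order == 0 else _h1_dv(v)
    out = u * dv
    if not raw:
        out = out / KIYONO_NORMALIZATION[order]
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# weight -> time-domain window
# ---------------------------------------------------------------------------

def transfer_to_time_kernel(weight, scale: float, T: int, tol: float = 1e-9) -> np.ndarray:
    """Recover the time-domain detrending window from a spectral weight.

    Any non-negative weight ``h(f)`` factors as ``h = (1 - h~)^2`` with
    ``h~(f) = 1 - sqrt(h(f))``; the time-domain window is the inverse
    DFT of ``h~``.  ``weight`` is either an array over ``f = 0..T//2``
    or a callable ``weight(f, scale, T)``.

    Returns a real length-``T`` sequence with lag 0 at index 0 and the
    circular symmetry ``kernel[tau] == kernel[T - tau]``.
    """
    grid = FrequencyGrid(T)
    f = grid.frequencies
    if callable(weight):
        h = np.asarray(weight(f, scale, T), dtype=float)
    else:
        h = np.asarray(weight, dtype=float)
    if h.shape != f.shape:
        raise ValueError(f"weight must have {f.size} one-sided values, got {h.shape}")
    if np.any(h < -tol):
        raise ValueError("spectral weight has negative values beyond tolerance")
    h = np.maximum(h, 0.0)
    h_tilde = 1.0 - np.sqrt(h)
    return np.fft.irfft(h_tilde, n=T)


# ---------------------------------------------------------------------------
# window objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowTransfer:
    """A detrending window identified by family and scale (samples).

    Subclasses implement ``transfer`` (h^_L(f), where defined),
    ``weight`` (the spectral weight multiplying ``|x^(f)|^2 / (4 sin^2)``)
    and ``dweight_dscale`` (its exact derivative in the scale), each
    vectorized over one-sided frequency indices.
    """

    scale: float

    family: str = field(default="abstract", init=False, repr=False)

    def __post_init__(self) -> None:
        _check_scale(self.scale)

    def transfer(self, f, T: int):
        raise NotImplementedError

    def weight(self, f, T: int):
        t = self.transfer(f, T)
        return (1.0 - np.asarray(t)) ** 2

    def dweight_dscale(self, f, T: int):
        raise NotImplementedError

    def with_scale(self, scale: float) -> "WindowTransfer":
        raise NotImplementedError


@dataclass(frozen=True)
class BoxcarWindow(WindowTransfer):
    family: str = field(default="boxcar", init=False, repr=False)

    def transfer(self, f, T: int):
        return boxcar_transfer(f, self.scale, T)

    def dweight_dscale(self, f, T: int):
        one_minus = 1.0 - np.asarray(boxcar_transfer(f, self.scale, T))
        return -2.0 * one_minus * np.asarray(boxcar_transfer_dscale(f, self.scale, T))

    def with_scale(self, scale: float) -> "BoxcarWindow":
        return BoxcarWindow(scale)


@dataclass(frozen=True)
class GaussianWindow(WindowTransfer):
    """Gaussian detrending window; ``scale`` is sigma in samples."""

    family: str = field(default="gaussian", init=False, repr=False)

    def transfer(self, f, T: int):
        return gaussian_transfer(f, self.scale, T)

    def weight(self, f, T: int):
        return _gaussian_one_minus_transfer(f, self.scale, T) ** 2

    def dweight_dscale(self, f, T: int):
        one_minus = _gaussian_one_minus_transfer(f, self.scale, T)
        return -2.0 * one_minus * np.asarray(gaussian_transfer_dscale(f, self.scale, T))

    def with_scale(self, scale: float) -> "GaussianWindow":
        return GaussianWindow(scale)


@dataclass(frozen=True)
class KiyonoWindow(WindowTransfer):
    order: int = 0

    family: str = field(default="kiyono", init=False, repr=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.order not in (0, 1):
            raise ValueError(f"order must be 0 or 1, got {self.order!r}")
        object.__setattr__(self, "family", f"kiyono{self.order}")

    def transfer(self, f, T: int):
        # effective transfer 1 - sqrt(h); the weight is defined directly
        return 1.0 - np.sqrt(np.asarray(self.weight(f, T)))

    def weight(self, f, T: int):
        return kiyono_weight(f, self.scale, T, self.order)

    def dweight_dscale(self, f, T: int):
        return kiyono_weight_dscale(f, self.scale, T, self.order)

    def with_scale(self, scale: float) -> "KiyonoWindow":
        return KiyonoWindow(scale, self.order)


@dataclass(frozen=True)
class CustomWindow(WindowTransfer):
    """User-supplied spectral weight ``weight_fn(f, scale, T)``.

    The weight must vanish at ``f = 0`` and be non-negative.  If no
    analytic ``dweight_fn`` is given, the scale derivative falls back to
    a centered finite difference in log-scale (relative step 1e-6).
    """

    weight_fn: Callable = None
    dweight_fn: Callable | None = None

    family: str = field(default="custom", init=False, repr=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.weight_fn is None:
            raise ValueError("CustomWindow requires a weight_fn")

    def _eval(self, f, T: int, scale: float) -> np.ndarray:
        fa = _check_freq(f, T)
        w = np.asarray(self.weight_fn(fa, scale, T), dtype=float)
        w0 = self.weight_fn(np.asarray([0.0]), scale, T)
        if abs(float(np.asarray(w0)[0])) > 1e-12:
            raise ValueError("custom weight must vanish at f = 0")
        if np.any(w < -1e-12):
            raise ValueError("custom weight must be non-negative")
        return np.maximum(w, 0.0)

    def transfer(self, f, T: int):
        return 1.0 - np.sqrt(self._eval(f, T, self.scale))

    def weight(self, f, T: int):
        return self._eval(f, T, self.scale)

    def dweight_dscale(self, f, T: int):
        fa = _check_freq(f, T)
        if self.dweight_fn is not None:
            return np.asarray(self.dweight_fn(fa, self.scale, T), dtype=float)
        eps = 1e-6
        hi = self._eval(fa, T, self.scale * (1.0 + eps))
        lo = self._eval(fa, T, self.scale * (1.0 - eps))
        return (hi - lo) / (2.0 * eps * self.scale)

    def with_scale(self, scale: float) -> "CustomWindow":
        return CustomWindow(scale, weight_fn=self.weight_fn, dweight_fn=self.dweight_fn)


def equivalent_scale(family: str, L: float) -> float:
    """Family scale parameter matching a boxcar of width ``L`` samples.

    The Gaussian uses ``sigma = L/sqrt(12)`` (equal standard deviation);
    all other families use ``L`` directly.
    """
    L = _check_scale(L, "L")
    return L * GAUSSIAN_SIGMA_RATIO if family == "gaussian" else L


def make_window(family: str, scale: float, *, scale_is_boxcar_width: bool = False,
                **kwargs) -> WindowTransfer:
    """Construct a window by family name.

    ``scale`` is the family's own parameter (width ``L`` for
    boxcar/kiyono, ``sigma`` for gaussian) unless
    ``scale_is_boxcar_width=True``, in which case it is interpreted as an
    equivalent boxcar width and converted via :func:`equivalent_scale`.
    """
    if family not in WINDOW_FAMILIES:
        raise ValueError(f"unknown window family {family!r}; choose from {WINDOW_FAMILIES}")
    if scale_is_boxcar_width:
        scale = equivalent_scale(family, scale)
    if family == "boxcar":
        return BoxcarWindow(scale)
    if family == "gaussian":
        return GaussianWindow(scale)
    if family == "kiyono0":
        return KiyonoWindow(scale, 0)
    if family == "kiyono1":
        return KiyonoWindow(scale, 1)
    return CustomWindow(scale, **kwargs)
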