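"""Synthetic test signals with exactly known scaling behavior.

Four signal classes exercise the analysis end to end:

* ``colored_noise`` — Gaussian noise synthesized in the spectral domain
  with E|x^(f)|^2 proportional to f^-gamma, so the expected DFA slope is
  exactly (1 + gamma)/2 (white gamma=0 -> 0.5, pink gamma=1 -> 1).
* ``weierstrass_series`` — a deterministic Weierstrass-type cosine sum
  at fractal dimension D in (1, 2); the graph is self-similar only under
  discrete scale changes (powers of the base b), so the local DFA slope
  oscillates log-periodically around the Hurst exponent H = 3 - D.
* ``roessler_series`` — the x coordinate of the chaotic Roessler system,
  time-rescaled so the dominant oscillation sits near a target frequency
  (~10 Hz); its amplitude envelope carries no long-range correlations,
  so envelope slopes decay to the white-noise level 0.5.
* ``filtered_noise_envelope`` — Hilbert envelope of FIR-bandpass-filtered
  white noise: the canonical null model for oscillation-amplitude
  analysis.  The filter's autocorrelation alone pushes small-scale
  slopes toward 2, declining to 0.5 once scales exceed the inverse
  bandwidth — the effect narrows bands stretch to ever larger scales.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .envelopes import band_envelope

__all__ = [
    "SimSpec",
    "simulate",
    "colored_noise",
    "weierstrass_series",
    "roessler_series",
    "filtered_noise_envelope",
    "ROESSLER_PARAMS",
]

#: the classic chaotic parameter set (a, b, c) of the Roessler system
ROESSLER_PARAMS = (0.2, 0.2, 5.7)

SIM_KINDS = ("colored_noise", "weierstrass", "roessler", "filtered_noise_envelope")


@dataclass(frozen=True)
class SimSpec:
    """Full record of a simulation: kind, size, rate, parameters, seed."""

    kind: str
    n: int
    fs: float
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SIM_KINDS:
            raise ValueError(f"kind must be one of {SIM_KINDS}, got {self.kind!r}")
        if self.n < 1000:
            raise ValueError(f"n must be >= 1000, got {self.n}")

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "n": self.n, "fs": self.fs,
             "seed": self.seed, "params": self.params},
            indent=2, sort_keys=True,
        )


def simulate(spec: SimSpec) -> np.ndarray:
    """Dispatch a SimSpec to its generator (identical spec -> identical series)."""
    p = dict(spec.params)
    if spec.kind == "colored_noise":
        return colored_noise(p.pop("gamma", 1.0), spec.n, fs=spec.fs, seed=spec.seed, **p)
    if spec.kind == "weierstrass":
        return weierstrass_series(p.pop("D", 1.6), spec.n, fs=spec.fs, seed=spec.seed, **p)
    if spec.kind == "roessler":
        return roessler_series(duration_s=spec.n / spec.fs, fs=spec.fs, seed=spec.seed, **p)
    if spec.kind == "filtered_noise_envelope":
        band = tuple(p.pop("band", (8.0, 13.0)))
        return filtered_noise_envelope(band, p.pop("fir_seconds", 1.0), spec.n,
                                       fs=spec.fs, seed=spec.seed, **p)
    raise AssertionError(spec.kind)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate (constant) simulation output")
    return (x - x.mean()) / sd


def colored_noise(gamma: float, n: int, fs: float = 1.0, seed: int | None = None) -> np.ndarray:
    """Power-law noise with E|x^(f)|^2 ~ f^-gamma, synthesized spectrally.

    Unit-variance complex Gaussian Fourier coefficients are scaled by
    f^(-gamma/2) (DC bin zero) and inverse-transformed, giving an exactly
    controlled spectral power law; the output is standardized to unit
    variance.  Valid for -1 < gamma < 3.
    """
    if not -1.0 < gamma < 3.0:
        raise ValueError(f"gamma must be in (-1, 3), got {gamma}")
    rng = np.random.default_rng(seed)
    nf = n // 2 + 1
    f = np.arange(nf, dtype=float)
    amp = np.zeros(nf)
    amp[1:] = f[1:] ** (-gamma / 2.0)
    coeff = (rng.standard_normal(nf) + 1j * rng.standard_normal(nf)) * amp
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real * np.sqrt(2.0)
    x = np.fft.irfft(coeff, n=n)
    return _standardize(x)


def weierstrass_series(D: float, n: int, fs: float = 1.0, seed: int | None = None,
                       base: float = 1.5, random_phases: bool = False) -> np.ndarray:
    """Weierstrass-type cosine sum at fractal dimension D in (1, 2).

    W(t) = sum_k b^(-k (2 - D)) cos(2 pi b^k t / n + phi_k), with the
    number of components chosen so the highest frequency reaches the
    Nyquist index n/2.  Component k has power ~ b^(-2k(2-D)) at frequency
    b^k, i.e. spectral density ~ f^-(5 - 2D), hence an expected DFA slope
    (Hurst exponent) of H = 3 - D.  Phases are zero by default (the
    classical deterministic graph); ``random_phases`` draws them from the
    seed.  Output standardized.
    """
    if not 1.0 < D < 2.0:
        raise ValueError(f"D must be in (1, 2), got {D}")
    if base <= 1.0:
        raise ValueError(f"base must exceed 1, got {base}")
    n_comp = int(np.floor(np.log(n / 2.0) / np.log(base))) + 1
    k = np.arange(n_comp)
    if random_phases:
        phases = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi, n_comp)
    else:
        phases = np.zeros(n_comp)
    t = np.arange(n, dtype=float)
    amps = base ** (-k * (2.0 - D))
    freqs = base**k / n  # cycles per sample
    w = np.zeros(n)
    for a, fr, ph in zip(amps, freqs, phases):
        w += a * np.cos(2.0 * np.pi * fr * t + ph)
    return _standardize(w)


def _roessler_rhs(t, state, a, b, c):
    x, y, z = state
    return (-y - z, x + a * y, b + z * (x - c))


def _integrate_roessler(t_eval, x0, params, rtol=1e-8, atol=1e-10) -> np.ndarray:
    sol = solve_ivp(
        _roessler_rhs, (0.0, float(t_eval[-1])), x0, t_eval=t_eval,
        args=tuple(params), method="DOP853", rtol=rtol, atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError("Roessler trajectory diverged; parameters may not be chaotic")
    if np.max(np.abs(sol.y)) > 1e6:
        raise RuntimeError("Roessler trajectory escaped; parameters may not be chaotic")
    return sol.y


def roessler_dominant_frequency(params=ROESSLER_PARAMS, x0=(1.0, 1.0, 0.0),
                                transient: float = 100.0, span: float = 400.0) -> float:
    """Dominant frequency (cycles per model-time unit) of x from a pilot run."""
    dt = 0.05
    t_eval = transient + np.arange(int(span / dt)) * dt
    x = _integrate_roessler(t_eval, list(x0), params)[0]
    x = x - x.mean()
    p = np.abs(np.fft.rfft(x * np.hanning(x.size))) ** 2
    p[0] = 0.0
    return float(np.argmax(p) / (x.size * dt))


def roessler_series(duration_s: float, fs: float, target_freq: float = 10.0,
                    params=ROESSLER_PARAMS, seed: int | None = None,
                    transient: float = 100.0) -> np.ndarray:
    """x coordinate of the chaotic Roessler system, rescaled to ~``target_freq``.

    The system dx/dt = -y - z, dy/dt = x + a y, dz/dt = b + z (x - c) is
    integrated with an adaptive 8th-order Runge-Kutta scheme; the first
    ``transient`` model-time units are discarded.  The time axis is then
    reinterpreted (linearly rescaled) so that the dominant spectral peak
    of x, estimated on a pilot integration, lands at ``target_freq`` Hz,
    and the trajectory is sampled at ``fs``.  The seed perturbs the
    initial condition only; the attractor statistics are unaffected.
    """
    if duration_s < 60.0:
        raise ValueError("duration must be at least 60 s")
    if fs < 10.0 * target_freq:
        raise ValueError("fs must be at least 10x the target frequency")
    rng = np.random.default_rng(seed)
    x0 = [1.0 + 1e-3 * rng.standard_normal(), 1.0 + 1e-3 * rng.standard_normal(), 0.0]
    f_model = roessler_dominant_frequency(params=params, x0=x0, transient=transient)
    n = int(round(duration_s * fs))
    # model time per output second: oscillation at f_model should appear at target_freq
    stretch = target_freq / f_model
    t_eval = transient + (np.arange(n) / fs) * stretch
    x = _integrate_roessler(t_eval, x0, params, rtol=1e-8, atol=1e-10)[0]
    return _standardize(x)


def filtered_noise_envelope(band: tuple[float, float], fir_seconds: float, n: int,
                            fs: float, seed: int | None = None) -> np.ndarray:
    """Hilbert envelope of FIR-bandpass-filtered white Gaussian noise.

    White noise is passed through a linear-phase FIR bandpass of
    ``fir_seconds`` duration; the analytic-signal magnitude is returned.
    The raw noise is uncorrelated beyond the filter length, yet the
    envelope's fluctuation slope stays above 0.5 for all scales up to
    roughly the inverse bandwidth.
    """
    if fir_seconds * fs < 64:
        raise ValueError("FIR filter must span at least 64 samples")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    return band_envelope(noise, fs, band, fir_seconds=fir_seconds)
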