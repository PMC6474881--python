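"""Band-limited amplitude envelopes and related statistics.

Oscillation-amplitude analysis extracts the instantaneous amplitude of a
band-limited rhythm (e.g. the 8-13 Hz alpha band) as the magnitude of
the analytic signal of the band-passed data; long-range temporal
correlation of that envelope is the quantity DFA is applied to.

Also provided: the spectral-peak SNR used to decide whether a component
carries a genuine oscillation, and the correction factor for the
standard error of a mean over correlated observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "PowerSpectrum1Hz",
    "CorrelationSummary",
    "band_envelope",
    "design_bandpass",
    "power_spectrum_1hz",
    "spectral_snr",
    "band_peak_snr",
    "sem_correction",
    "envelope_correlation",
]


@dataclass(frozen=True)
class PowerSpectrum1Hz:
    """Power on a uniform 1 Hz frequency grid."""

    freqs: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs.shape != self.P.shape:
            raise ValueError("freqs and P must match")
        df = np.diff(self.freqs)
        if df.size and not np.allclose(df, 1.0):
            raise ValueError("grid must have uniform 1 Hz spacing")
        if np.any(self.P < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class CorrelationSummary:
    """Number of observations and their mean off-diagonal correlation."""

    N: int
    rho_bar: float

    def __post_init__(self) -> None:
        lo = -1.0 / (self.N - 1) if self.N > 1 else -1.0
        if not lo - 1e-12 <= self.rho_bar <= 1.0 + 1e-12:
            raise ValueError(
                f"rho_bar={self.rho_bar} violates positive-semidefiniteness "
                f"bound [{lo}, 1] for N={self.N}"
            )


def design_bandpass(fs: float, band: tuple[float, float], fir_seconds: float = 1.0) -> np.ndarray:
    """Linear-phase FIR bandpass (Hamming window method, odd length)."""
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < fs/2 = {fs / 2}")
    numtaps = int(round(fir_seconds * fs))
    if numtaps < 3:
        raise ValueError("FIR duration too short for this sampling rate")
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def band_envelope(x, fs: float, band: tuple[float, float], fir_seconds: float = 1.0) -> np.ndarray:
    """Amplitude envelope of ``x`` in a frequency band.

    The series is band-passed with a linear-phase FIR filter applied
    without net delay (symmetric taps, 'same'-mode convolution), then the
    magnitude of the analytic (Hilbert-transformed) signal is returned.
    Output length equals input length; edges within half a filter length
    are attenuated by the truncated convolution.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    taps = design_bandpass(fs, band, fir_seconds)
    filtered = signal.fftconvolve(x, taps, mode="same")
    return np.abs(signal.hilbert(filtered))


def power_spectrum_1hz(x, fs: float) -> PowerSpectrum1Hz:
    """Welch power spectrum with 1 s segments, i.e. 1 Hz resolution."""
    nperseg = int(round(fs))
    if nperseg < 2:
        raise ValueError("sampling rate too low for 1 Hz resolution")
    freqs, P = signal.welch(np.asarray(x, dtype=float), fs=fs, nperseg=nperseg)
    return PowerSpectrum1Hz(freqs=freqs, P=P)


def spectral_snr(P: PowerSpectrum1Hz, f: float, delta_f: float = 2.0) -> float:
    """Peak power above the locally interpolated background.

    The background at ``f`` is N(f) = (P(f + delta_f) + P(f - delta_f))/2
    and SNR(f) = (P(f) - N(f)) / N(f); negative values indicate a trough.
    """
    freqs = P.freqs
    for target in (f - delta_f, f, f + delta_f):
        if target < freqs[0] - 1e-9 or target > freqs[-1] + 1e-9:
            raise ValueError(f"frequency {target} Hz outside the spectrum grid")
    idx = int(round(f - freqs[0]))
    off = int(round(delta_f))
    noise = 0.5 * (P.P[idx - off] + P.P[idx + off])
    if noise <= 0.0:
        raise ValueError("background power is zero; SNR undefined")
    return float((P.P[idx] - noise) / noise)


def band_peak_snr(P: PowerSpectrum1Hz, band: tuple[float, float], delta_f: float = 2.0) -> float:
    """Maximum spectral-peak SNR across a band (for selection thresholds,
    e.g. 'contains substantial alpha rhythm' at SNR > 5)."""
    lo, hi = band
    fs_in_band = P.freqs[(P.freqs >= lo) & (P.freqs <= hi)]
    if fs_in_band.size == 0:
        raise ValueError(f"no 1 Hz bins inside band {band}")
    return max(spectral_snr(P, float(f), delta_f) for f in fs_in_band)


def sem_correction(N: int, rho_bar: float) -> float:
    """SEM inflation factor for correlated observations.

    For N observations with mean off-diagonal correlation rho_bar the
    standard error of their mean is the naive SEM times
    lambda = sqrt(1 + (N - 1) rho_bar): 1 for independent observations,
    sqrt(N) for fully redundant ones.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    arg = 1.0 + (N - 1) * rho_bar
    if arg < 0.0:
        raise ValueError(
            f"1 + (N-1) rho_bar = {arg} < 0: rho_bar below the "
            "positive-semidefiniteness bound"
        )
    return float(np.sqrt(arg))


def envelope_correlation(envelopes: np.ndarray) -> CorrelationSummary:
    """Mean off-diagonal correlation across channels (rows) of envelopes.

    Used as a redundancy proxy when correcting the SEM of quantities
    derived per channel: rho_bar = mean of rho_ij over i != j.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.ndim != 2 or env.shape[0] < 2:
        raise ValueError("need a (n_channels >= 2, n_samples) array")
    C = np.corrcoef(env)
    N = C.shape[0]
    rho_bar = float((C.sum() - np.trace(C)) / (N * (N - 1)))
    return CorrelationSummary(N=N, rho_bar=rho_bar)
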