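"""Scikit-learn compatible estimators for fluctuation analysis.

``SpectralDFA`` and ``ClassicalDFA`` turn a batch of time series
(rows = independent series/channels, columns = time points) into
fluctuation and local-slope features over a log-spaced scale grid.  They
follow the sklearn transformer contract (``fit``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes)
and compose with pipelines and model selection, e.g. feeding Hurst
profiles into a downstream classifier.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .fluctuation import default_scale_grid, fourier_fluctuation, spectrum_half
from .slopes import finite_difference_slope, fourier_slope, trust_mask
from .fluctuation import classical_dfa

__all__ = ["SpectralDFA", "ClassicalDFA"]


def _check_series_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError(f"expected (n_series, n_timepoints), got shape {X.shape}")
    if X.shape[1] < 16:
        raise ValueError("series too short for fluctuation analysis")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    return X


class _BaseDFA(TransformerMixin, BaseEstimator):
    def __init__(self, fs=1.0, scales=None, n_scales=130,
                 min_scale_s=0.01, max_scale_s=200.0):
        self.fs = fs
        self.scales = scales
        self.n_scales = n_scales
        self.min_scale_s = min_scale_s
        self.max_scale_s = max_scale_s

    def _grid(self, T: int) -> np.ndarray:
        if self.scales is not None:
            g = np.asarray(self.scales, dtype=float)
            if np.any(np.diff(g) <= 0) or np.any(g <= 0):
                raise ValueError("scales must be positive and strictly increasing")
            return g
        return default_scale_grid(T, fs=self.fs, n=self.n_scales,
                                  min_seconds=self.min_scale_s,
                                  max_seconds=self.max_scale_s)

    def fit(self, X, y=None):
        X = _check_series_matrix(X)
        self.n_features_in_ = X.shape[1]
        self.scales_ = self._grid(X.shape[1])
        self.scales_seconds_ = self.scales_ / self.fs
        self.trusted_ = trust_mask(self.scales_, X.shape[1])
        self.fluctuation_, self.slope_ = self._curves(X, self.scales_)
        return self

    def transform(self, X):
        """Local-slope features, shape (n_series, n_scales)."""
        check_is_fitted(self, "scales_")
        X = _check_series_matrix(X)
        return self._curves(X, self.scales_)[1]

    def _curves(self, X, scales):
        raise NotImplementedError


class SpectralDFA(_BaseDFA):
    """Stationary DFA in the Fourier domain with analytic local slopes.

    Parameters
    ----------
    window : str
        Detrending window family: 'boxcar', 'gaussian', 'kiyono0' or
        'kiyono1'.  Scales are equivalent boxcar widths; the Gaussian is
        evaluated at sigma = L/sqrt(12).
    fs : float
        Sampling rate in Hz.
    scales : array-like or None
        Explicit scale grid in samples; default is ``n_scales``
        log-spaced values between ``min_scale_s`` and ``max_scale_s``
        seconds, clamped to [3 samples, T/4].

    Attributes
    ----------
    scales_ : ndarray, scale grid in samples
    fluctuation_ : ndarray (n_series, n_scales), F at each scale
    slope_ : ndarray (n_series, n_scales), analytic d log F/d log L
    trusted_ : bool ndarray, scales inside the trustworthy region

    Examples
    --------
    >>> import numpy as np
    >>> from stationary_dfa import SpectralDFA
    >>> x = np.random.default_rng(0).standard_normal(4096)
    >>> est = SpectralDFA(window="boxcar", fs=64.0).fit(x)
    >>> round(float(np.median(est.slope_)), 2)  # white noise -> about 0.5
    0.51
    """

    def __init__(self, window="boxcar", fs=1.0, scales=None, n_scales=130,
                 min_scale_s=0.01, max_scale_s=200.0):
        super().__init__(fs=fs, scales=scales, n_scales=n_scales,
                         min_scale_s=min_scale_s, max_scale_s=max_scale_s)
        self.window = window

    def _curves(self, X, scales):
        F = np.empty((X.shape[0], scales.size))
        S = np.empty_like(F)
        for i, row in enumerate(X):
            spec = spectrum_half(row, fs=self.fs)
            F[i] = [fourier_fluctuation(spec, s, self.window) for s in scales]
            S[i] = [fourier_slope(spec, s, self.window) for s in scales]
        return F, S


class ClassicalDFA(_BaseDFA):
    """Classical segment-wise DFA (linear detrending, disjoint segments).

    Scales are rounded to integers; slopes come from finite differences
    of log F, which for this route are only meaningful after smoothing or
    interval fits — the estimator exists mainly as the reference against
    which the stationary route is compared.
    """

    def _grid(self, T: int) -> np.ndarray:
        g = super()._grid(T)
        g = np.unique(np.round(g).astype(int))
        return g[g >= 4].astype(float)

    def _curves(self, X, scales):
        F = np.empty((X.shape[0], scales.size))
        S = np.empty_like(F)
        for i, row in enumerate(X):
            curve = classical_dfa(row, scales.astype(int), fs=self.fs)
            F[i] = curve.F
            S[i] = finite_difference_slope(curve).slope
        return F, S
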