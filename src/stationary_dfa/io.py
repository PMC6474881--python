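"""Readers, writers, run configuration and the batch analysis driver.

Input series are plain CSV/TSV, one column per channel, optional header;
the sampling rate is supplied alongside (files carry no rate metadata).
Output curves are tidy CSV with one row per (method, window, channel,
scale); every run writes a JSON manifest recording the full effective
configuration, including defaulted values, so it can be reconstructed
from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .fluctuation import FluctuationCurve, default_scale_grid, fluctuation_curve
from .slopes import SlopeCurve, slope_curve

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_curves",
    "read_curves",
    "normalize_curves",
    "run_analysis",
]

logger = logging.getLogger("stationary_dfa")

CURVE_COLUMNS = ["method", "window", "channel", "scale_samples", "scale_seconds", "F"]
SLOPE_COLUMNS = ["window", "channel", "scale_samples", "scale_seconds", "slope", "trusted"]


def read_timeseries(path, fs: float) -> tuple[np.ndarray, list[str]]:
    """Load a CSV/TSV series file: (T, n_channels) array + channel names.

    Delimiter is inferred from the extension ('.tsv' -> tab); a header
    row is detected by non-numeric first line.  Missing values are an
    error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    first = path.open().readline()
    has_header = False
    for tok in first.strip().split(sep):
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data")
    names = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    return values, names


def write_curves(curves: list[tuple[FluctuationCurve, str]], path) -> None:
    """Write fluctuation curves as tidy CSV (one row per scale)."""
    frames = [c.to_frame(channel=ch) for c, ch in curves]
    pd.concat(frames, ignore_index=True)[CURVE_COLUMNS].to_csv(path, index=False)


def read_curves(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_slopes(slopes: list[tuple[SlopeCurve, str]], path) -> None:
    frames = [s.to_frame(channel=ch) for s, ch in slopes]
    pd.concat(frames, ignore_index=True)[SLOPE_COLUMNS].to_csv(path, index=False)


def normalize_curves(curves: list[FluctuationCurve],
                     range_s: tuple[float, float] = (0.1, 10.0)) -> list[FluctuationCurve]:
    """Divide each F by its own mean over a scale range (seconds).

    Removes the method-dependent global factor so curves from different
    routes are directly comparable; slopes are unchanged.
    """
    lo, hi = range_s
    out = []
    for c in curves:
        sel = (c.scales_seconds >= lo) & (c.scales_seconds <= hi)
        if not sel.any():
            raise ValueError(f"curve has no scales inside [{lo}, {hi}] s")
        out.append(FluctuationCurve(scales=c.scales, F=c.F / c.F[sel].mean(),
                                    method=c.method, window=c.window, fs=c.fs))
    return out


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input: str
    fs: float
    methods: tuple[str, ...] = ("fourier",)
    windows: tuple[str, ...] = ("boxcar",)
    min_scale_s: float = 0.01
    max_scale_s: float = 200.0
    n_scales: int = 130
    out_dir: str = "."
    seed: int = 0
    compute_slopes: bool = True
    normalize_range_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")
        if not self.windows:
            raise ValueError("at least one window is required")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_analysis(config: RunConfig) -> dict:
    """Run fluctuation/slope analysis per channel, method and window.

    Writes one curve CSV per (method, window), one slope CSV per window
    for the fourier method, and a JSON manifest; returns a summary dict
    with the paths written.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, names = read_timeseries(config.input, config.fs)
    T = X.shape[0]
    scales = default_scale_grid(T, fs=config.fs, n=config.n_scales,
                                min_seconds=config.min_scale_s,
                                max_seconds=config.max_scale_s)
    written: list[str] = []
    for method in config.methods:
        windows = config.windows if method == "fourier" else ("n/a",)
        for window in windows:
            curves = []
            for j, name in enumerate(names):
                kwargs = {"window": window} if method == "fourier" else {}
                c = fluctuation_curve(X[:, j], scales, fs=config.fs, method=method, **kwargs)
                if config.normalize_range_s is not None:
                    c = normalize_curves([c], config.normalize_range_s)[0]
                curves.append((c, name))
            tag = f"{method}" + (f"_{window}" if window != "n/a" else "")
            path = out_dir / f"fluctuation_{tag}.csv"
            write_curves(curves, path)
            written.append(str(path))
            logger.info("wrote %s (%d channels)", path, len(curves))
    if config.compute_slopes and "fourier" in config.methods:
        for window in config.windows:
            slopes = [(slope_curve(X[:, j], scales, window=window, fs=config.fs), name)
                      for j, name in enumerate(names)]
            path = out_dir / f"slope_fourier_{window}.csv"
            write_slopes(slopes, path)
            written.append(str(path))
            logger.info("wrote %s", path)
    manifest = {
        "config": _jsonable(asdict(config)),
        "version": _pkg_version,
        "n_samples": int(T),
        "channels": names,
        "scales_samples": [float(s) for s in scales],
        "outputs": written,
        "elapsed_s": round(time.time() - t0, 3),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("analysis finished in %.3f s", manifest["elapsed_s"])
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
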