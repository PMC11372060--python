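"""Growth-trend removal, mean normalization and smoothing of well traces.

The signal-isolation stage: a degree-4 polynomial is fitted by ordinary least
squares to each raw trace — excluding the first 3 h, where start-up artifacts
dominate — and its prediction is subtracted at *all* time points.  The
residual is normalized by subtracting its arithmetic mean and then smoothed
with a uniform moving-average kernel (40 samples at 5-min sampling) using
zero-padded "same" convolution, edge bias included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FitError, ShapeError
from .plate_io import PlateSeries, WellTrace


@dataclass(frozen=True)
class DetrendConfig:
    """Detrending/smoothing parameters.

    degree : polynomial degree of the growth trend (default 4)
    exclude_before : hours excluded from the *fit* (default 3 h); the trend is
        still subtracted there
    kernel_size : moving-average width in samples (default 40, i.e. 3 h 20 min
        at 5-min sampling)
    """

    degree: int = 4
    exclude_before: float = 3.0
    kernel_size: int = 40

    def __post_init__(self):
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.exclude_before < 0:
            raise ValueError("exclude_before must be >= 0")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")


@dataclass
class ProcessedTrace:
    """Detrended, mean-subtracted and smoothed version of one well."""

    well_id: str
    strain: str
    normalized: np.ndarray
    smoothed: np.ndarray
    trend_coeffs: np.ndarray  # lowest order first
    subtracted_mean: float


def fit_trend(values, times, cfg: DetrendConfig = DetrendConfig()) -> np.ndarray:
    """OLS polynomial fit of the growth trend, using only t >= exclude_before.

    Coefficients are returned in the monomial basis, lowest order first.  The
    fit itself runs on a scaled time domain (a degree-4 design on t up to 84 h
    is badly conditioned in raw monomials) and is converted back afterwards.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise ShapeError("values and times must have equal length")
    mask = times >= cfg.exclude_before
    t_inc, y_inc = times[mask], values[mask]
    if t_inc.size <= cfg.degree:
        raise FitError(
            f"need more than degree={cfg.degree} points after excluding "
            f"t < {cfg.exclude_before} h; got {t_inc.size}"
        )
    if np.unique(t_inc).size <= cfg.degree:
        raise FitError("rank-deficient design: too few distinct time points")
    # Polynomial.fit maps times to [-1, 1] internally; convert() restores monomials.
    poly = np.polynomial.Polynomial.fit(t_inc, y_inc, deg=cfg.degree)
    return poly.convert().coef


def detrend_normalize(values, times, coeffs) -> tuple[np.ndarray, float]:
    """Subtract the fitted trend at all time points, then subtract the
    residual's arithmetic mean.  Returns (normalized, subtracted_mean)."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise ShapeError("values and times must have equal length")
    residual = values - np.polynomial.polynomial.polyval(times, np.asarray(coeffs, float))
    mean = float(residual.mean())
    return residual - mean, mean


def smooth(normalized, kernel_size: int) -> np.ndarray:
    """Zero-padded 'same' moving average with a uniform kernel of weight 1/k.

    Output length equals input length; the first and last ~k/2 samples carry
    the usual zero-padding edge bias, reproduced deliberately.
    """
    x = np.asarray(normalized, dtype=float)
    k = int(kernel_size)
    if k < 1:
        raise ValueError("kernel_size must be >= 1")
    if k > x.size:
        warnings.warn(
            f"kernel_size {k} exceeds series length {x.size}; smoothing anyway",
            stacklevel=2,
        )
    full = np.convolve(x, np.ones(k) / k, mode="full")
    start = (k - 1) // 2
    return full[start : start + x.size]


def preprocess_well(
    trace: WellTrace, times, cfg: DetrendConfig = DetrendConfig()
) -> ProcessedTrace:
    """Full signal isolation for one well: fit trend, detrend+normalize, smooth."""
    coeffs = fit_trend(trace.values, times, cfg)
    normalized, mean = detrend_normalize(trace.values, times, coeffs)
    return ProcessedTrace(
        well_id=trace.well_id,
        strain=trace.strain,
        normalized=normalized,
        smoothed=smooth(normalized, cfg.kernel_size),
        trend_coeffs=coeffs,
        subtracted_mean=mean,
    )


def preprocess_series(
    series: PlateSeries, cfg: DetrendConfig = DetrendConfig()
) -> list[ProcessedTrace]:
    return [preprocess_well(w, series.times, cfg) for w in series.wells]
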