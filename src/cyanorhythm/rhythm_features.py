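"""Peak/trough detection and dampened-oscillation phenotype metrics.

For strains whose rhythm decays and is not well described by a single cosine,
the phenotype is summarized by features of the first oscillation cycle:

* first-cycle period = 2 * |t(first peak) - t(first trough)|  (the trough-to-
  peak distance is half a cycle; the absolute value makes the estimate
  independent of which extremum comes first);
* phase shift of a mutant's first peak relative to a reference strain,
  shift = mean_peak_time[mutant] - mean_peak_time[reference], with error
  boundary SD[mutant] + SD[reference];
* relative amplitude = mean_peak_height[mutant] / mean_peak_height[reference],
  with error boundary SD_m/height_m + SD_r/height_r (implemented literally;
  an optional flag multiplies by the ratio for the propagated-error variant).

Peak detection is prominence-based: candidate local maxima are filtered by a
minimum height, thinned so surviving peaks are at least ``min_distance``
samples apart (highest peak kept first), and optionally filtered by the full
width measured at half prominence (linear interpolation between samples).
Distances/widths are stored as sample counts at the reference 5-min grid
(150 samples = 12.5 h, 65 samples ~ 5.4 h) and rescaled when the actual grid
spacing differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .errors import DomainError, FeatureError

#: Reference sampling interval (hours) at which sample-count parameters are quoted.
REFERENCE_DT_H = 1.0 / 12.0


@dataclass(frozen=True)
class PeakParams:
    """Peak-detection parameters.

    min_distance / min_width are sample counts at 5-min sampling and are
    rescaled by the actual grid spacing.  min_height=None means the adaptive
    threshold mean(signal) + 0.2 * max(signal).
    """

    min_distance: int = 150
    min_height: float | None = 50.0
    min_width: float | None = None
    reference_dt: float = REFERENCE_DT_H
    #: samples dropped from each end of the search window (0 = whole trace);
    #: set to half the smoothing kernel to skip the zero-padding edge bias
    edge_exclude: int = 0

    def __post_init__(self):
        if self.min_distance < 1:
            raise DomainError("min_distance must be >= 1")
        if self.min_width is not None and self.min_width < 0:
            raise DomainError("min_width must be >= 0")
        if self.edge_exclude < 0:
            raise DomainError("edge_exclude must be >= 0")

    def scaled_distance(self, dt: float | None) -> int:
        if dt is None or dt <= 0:
            return self.min_distance
        return max(1, int(round(self.min_distance * self.reference_dt / dt)))

    def scaled_width(self, dt: float | None) -> float | None:
        if self.min_width is None:
            return None
        if dt is None or dt <= 0:
            return self.min_width
        return self.min_width * self.reference_dt / dt


#: Defaults for first-cycle period estimation (first trough and peak).
PERIOD_PEAK_PARAMS = PeakParams(min_distance=150, min_height=50.0, min_width=None)

#: Defaults for first-peak phase/amplitude features.
FIRST_PEAK_PARAMS = PeakParams(min_distance=150, min_height=None, min_width=65.0)


@dataclass
class PeakSet:
    """Detected extrema: positions, times, heights, prominences, widths."""

    indices: np.ndarray
    times: np.ndarray | None
    heights: np.ndarray
    prominences: np.ndarray
    widths: np.ndarray  # full width at half prominence, in samples

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class StrainFirstPeak:
    """Per-strain first-peak summary across replicate wells."""

    strain: str
    n_wells: int
    peak_time_mean: float
    peak_time_sd: float
    peak_height_mean: float
    peak_height_sd: float


@dataclass
class ComparisonResult:
    """Mutant vs reference first-peak comparison with error boundaries."""

    phase_shift: float
    phase_shift_err: float
    relative_amplitude: float
    relative_amplitude_err: float


@dataclass
class FirstPeriodStats:
    """Per-strain first-cycle periods plus their mean/median/sample SD."""

    strain: str
    periods: list[float]
    mean: float
    median: float
    sd: float
    n_failed: int = 0


def _grid_dt(times) -> float | None:
    if times is None:
        return None
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return None
    return float(times[1] - times[0])


def _resolve_height(signal: np.ndarray, params: PeakParams) -> float:
    if params.min_height is not None:
        return params.min_height
    return float(signal.mean() + 0.2 * signal.max())


def find_peaks(values, params: PeakParams = PERIOD_PEAK_PARAMS, times=None) -> PeakSet:
    """Local maxima filtered by height, thinned by distance, optionally
    filtered by width at half prominence.  Plateaus collapse to their
    floor-midpoint sample.  An empty PeakSet is a valid result."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        return PeakSet(
            indices=np.array([], int), times=None if times is None else np.array([]),
            heights=np.array([]), prominences=np.array([]), widths=np.array([]),
        )
    dt = _grid_dt(times)
    height = _resolve_height(x, params)
    kwargs = dict(height=height, distance=params.scaled_distance(dt))
    width = params.scaled_width(dt)
    if width is not None:
        kwargs["width"] = width
        kwargs["rel_height"] = 0.5
    idx, props = _sig.find_peaks(x, **kwargs)
    if width is not None:
        prominences = props["prominences"]
        widths = props["widths"]
    else:
        prominences = _sig.peak_prominences(x, idx)[0]
        widths = _sig.peak_widths(x, idx, rel_height=0.5)[0]
    if params.edge_exclude > 0:
        keep = (idx >= params.edge_exclude) & (idx < x.size - params.edge_exclude)
        idx, prominences, widths = idx[keep], prominences[keep], widths[keep]
    return PeakSet(
        indices=idx,
        times=None if times is None else np.asarray(times, float)[idx],
        heights=x[idx],
        prominences=prominences,
        widths=widths,
    )


def find_troughs(values, params: PeakParams = PERIOD_PEAK_PARAMS, times=None) -> PeakSet:
    """Peaks of the negated signal; heights are reported as the original
    (negative) values, while min_height applies to the negated signal."""
    x = np.asarray(values, dtype=float)
    peaks = find_peaks(-x, params, times=times)
    peaks.heights = -peaks.heights
    return peaks


def first_cycle_period(
    values, times, params: PeakParams = PERIOD_PEAK_PARAMS
) -> float:
    """Twice the absolute time from the first trough to the first peak."""
    troughs = find_troughs(values, params, times=times)
    peaks = find_peaks(values, params, times=times)
    if len(troughs) == 0 or len(peaks) == 0:
        raise FeatureError(
            f"no {'trough' if len(troughs) == 0 else 'peak'} detected "
            "(signal too flat for the configured height/distance?)"
        )
    return 2.0 * abs(float(peaks.times[0]) - float(troughs.times[0]))


def first_peak_features(
    values, times, params: PeakParams = FIRST_PEAK_PARAMS
) -> tuple[float, float]:
    """(time, height) of the earliest peak passing the distance/width/height
    filters; raises FeatureError when no peak qualifies."""
    peaks = find_peaks(values, params, times=times)
    if len(peaks) == 0:
        raise FeatureError("no qualifying first peak")
    return float(peaks.times[0]), float(peaks.heights[0])


def summarize_strain(
    strain: str, peak_times: Sequence[float], peak_heights: Sequence[float]
) -> StrainFirstPeak:
    """Arithmetic mean and sample SD (n-1 denominator; 0 when n = 1) of the
    replicate wells' first-peak times and heights."""
    t = np.asarray(peak_times, dtype=float)
    h = np.asarray(peak_heights, dtype=float)
    if t.size < 1 or t.size != h.size:
        raise DomainError("need >= 1 well with matching times and heights")
    sd = (lambda v: float(v.std(ddof=1)) if v.size > 1 else 0.0)
    return StrainFirstPeak(
        strain=strain,
        n_wells=int(t.size),
        peak_time_mean=float(t.mean()),
        peak_time_sd=sd(t),
        peak_height_mean=float(h.mean()),
        peak_height_sd=sd(h),
    )


def phase_shift(
    mutant: StrainFirstPeak, reference: StrainFirstPeak
) -> tuple[float, float]:
    """First-peak phase shift (hours) and its error boundary (sum of SDs)."""
    shift = mutant.peak_time_mean - reference.peak_time_mean
    return shift, mutant.peak_time_sd + reference.peak_time_sd


def relative_amplitude(
    mutant: StrainFirstPeak,
    reference: StrainFirstPeak,
    propagate: bool = False,
) -> tuple[float, float]:
    """First-peak height ratio mutant/reference and its error boundary
    (sum of relative SDs as printed; ``propagate=True`` multiplies the sum
    by the ratio for the standard propagated-error variant)."""
    if reference.peak_height_mean == 0 or mutant.peak_height_mean == 0:
        raise DomainError("peak heights must be nonzero for a relative amplitude")
    ratio = mutant.peak_height_mean / reference.peak_height_mean
    err = (
        mutant.peak_height_sd / mutant.peak_height_mean
        + reference.peak_height_sd / reference.peak_height_mean
    )
    if propagate:
        err *= abs(ratio)
    return ratio, abs(err)


def compare_to_reference(
    mutant: StrainFirstPeak, reference: StrainFirstPeak
) -> ComparisonResult:
    shift, shift_err = phase_shift(mutant, reference)
    ratio, ratio_err = relative_amplitude(mutant, reference)
    return ComparisonResult(
        phase_shift=shift, phase_shift_err=shift_err,
        relative_amplitude=ratio, relative_amplitude_err=ratio_err,
    )


def first_period_stats(
    strain: str,
    well_signals: Sequence[np.ndarray],
    times,
    params: PeakParams = PERIOD_PEAK_PARAMS,
) -> FirstPeriodStats:
    """First-cycle period per well plus mean/median/sample SD; wells where
    the trough or peak cannot be detected are skipped (and counted)."""
    periods: list[float] = []
    n_failed = 0
    for sig in well_signals:
        try:
            periods.append(first_cycle_period(sig, times, params))
        except FeatureError:
            n_failed += 1
    if not periods:
        raise FeatureError(f"strain {strain!r}: no well yielded a first-cycle period")
    arr = np.asarray(periods)
    return FirstPeriodStats(
        strain=strain,
        periods=periods,
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n_failed=n_failed,
    )
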