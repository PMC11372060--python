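"""Synthetic plate-reader experiments with the statistical structure the
analysis pipeline assumes.

Each simulated well is

    y(t) = trend(t) + transient(t) + A0 * exp(-lambda*t) * cos(2*pi*t/P + phi0) + eps

with ``trend`` either a polynomial (coefficients lowest order first) or a
logistic growth curve, ``transient`` a fast-decaying start-up artifact
(``c * exp(-t/tau)``, gone within the first ~3 h for the default tau of 1 h),
and ``eps`` i.i.d. Gaussian noise.  The generator exists so every downstream
stage — detrending, harmonic fitting, peak metrics, strain statistics — can be
exercised against known ground truth.

Reproducibility: the per-well seed is ``numpy.random.SeedSequence((experiment
seed, well index))``, so a given experiment seed always yields bit-identical
plates, independent of strain naming or dict ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import ParamError, SpecError
from .plate_io import PlateSeries, WellTrace

#: 5-minute sampling interval in hours (the reference plate-reader grid).
DT_5MIN_H = 1.0 / 12.0

#: Default experiment duration in hours.
DEFAULT_DURATION_H = 84.0

#: Monotone quartic growth trend (backscatter a.u.), lowest order first.
#: Rises from ~200 to ~3200 a.u. over 84 h, mimicking a dense culture.
DEFAULT_QUARTIC_TREND = (200.0, 20.0, 0.5, -5e-3, 1.5e-5)


@dataclass(frozen=True)
class LogisticTrend:
    """Logistic growth curve K / (1 + exp(-r (t - t_mid)))."""

    carrying_capacity: float
    rate: float
    midpoint: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.carrying_capacity / (1.0 + np.exp(-self.rate * (t - self.midpoint)))


TrendSpec = Union[Sequence[float], LogisticTrend]


@dataclass(frozen=True)
class WellSimParams:
    """Ground-truth parameters for one simulated well.

    Parameters
    ----------
    trend : sequence of float or LogisticTrend
        Growth trend; polynomial coefficients lowest order first (degree <= 4)
        or a logistic curve.
    osc_amplitude : float
        Oscillation amplitude A0 (backscatter units, >= 0).
    period : float
        Oscillation period P in hours (> 0).
    phase : float
        Phase angle phi0 in radians.
    damping : float
        Exponential damping rate lambda in 1/h (>= 0; 0 = self-sustained).
    noise_sd : float
        SD of i.i.d. Gaussian noise (backscatter units, >= 0).
    transient_amplitude : float
        Amplitude of the start-up transient c * exp(-t/tau) (>= 0).
    transient_tau : float
        Transient decay time in hours (default 1 h, i.e. gone within ~3 h).
    """

    trend: TrendSpec = (0.0,)
    osc_amplitude: float = 0.0
    period: float = 26.0
    phase: float = 0.0
    damping: float = 0.0
    noise_sd: float = 0.0
    transient_amplitude: float = 0.0
    transient_tau: float = 1.0

    def __post_init__(self):
        if self.period <= 0:
            raise ParamError("period must be > 0")
        if self.osc_amplitude < 0:
            raise ParamError("osc_amplitude must be >= 0")
        if self.damping < 0:
            raise ParamError("damping must be >= 0")
        if self.noise_sd < 0:
            raise ParamError("noise_sd must be >= 0")
        if self.transient_amplitude < 0:
            raise ParamError("transient_amplitude must be >= 0")
        if self.transient_tau <= 0:
            raise ParamError("transient_tau must be > 0")
        if not isinstance(self.trend, LogisticTrend):
            coeffs = tuple(float(c) for c in self.trend)
            if len(coeffs) == 0 or len(coeffs) > 5:
                raise ParamError("polynomial trend must have 1-5 coefficients (degree <= 4)")
            object.__setattr__(self, "trend", coeffs)

    def trend_values(self, times: np.ndarray) -> np.ndarray:
        if isinstance(self.trend, LogisticTrend):
            return self.trend(times)
        return np.polynomial.polynomial.polyval(times, self.trend)


@dataclass(frozen=True)
class ExperimentSpec:
    """A whole plate: per-strain parameters, replicate count, grid, seed."""

    strains: Mapping[str, WellSimParams]
    replicates: int = 5
    duration: float = DEFAULT_DURATION_H
    dt: float = DT_5MIN_H
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise SpecError("replicates must be >= 1")
        if self.duration <= 0 or self.dt <= 0:
            raise SpecError("duration and dt must be > 0")
        if int(self.duration / self.dt) + 1 < 2:
            raise SpecError("duration/dt must yield at least 2 samples")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt


def simulate_well(params: WellSimParams, times, seed) -> np.ndarray:
    """Simulate one well on the given hour grid; identical seed, identical trace."""
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    omega = 2.0 * math.pi / params.period
    signal = (
        params.trend_values(times)
        + params.transient_amplitude * np.exp(-times / params.transient_tau)
        + params.osc_amplitude
        * np.exp(-params.damping * times)
        * np.cos(omega * times + params.phase)
    )
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=times.size)
    return signal


def simulate_experiment(spec: ExperimentSpec) -> PlateSeries:
    """Simulate every replicate of every strain on one shared grid.

    Well ids are ``{strain}_{replicate}``; the per-well seed is
    ``SeedSequence((spec.seed, well_index))`` with wells enumerated in
    strain-then-replicate order.
    """
    times = spec.time_grid()
    wells: list[WellTrace] = []
    seen_ids: set[str] = set()
    well_index = 0
    for strain, params in spec.strains.items():
        for rep in range(spec.replicates):
            well_id = f"{strain}_{rep + 1}"
            if well_id in seen_ids:
                raise SpecError(f"duplicate well id {well_id!r}")
            seen_ids.add(well_id)
            seed = np.random.SeedSequence((spec.seed, well_index))
            wells.append(
                WellTrace(well_id=well_id, strain=strain, values=simulate_well(params, times, seed))
            )
            well_index += 1
    return PlateSeries(times=times, wells=wells)


def reference_preset(noise_sd: float = 8.0) -> WellSimParams:
    """Self-sustained ~26 h oscillator on a quartic growth trend (wild-type-like)."""
    return WellSimParams(
        trend=DEFAULT_QUARTIC_TREND,
        osc_amplitude=80.0,
        period=26.0,
        phase=1.0,
        damping=0.0,
        noise_sd=noise_sd,
        transient_amplitude=40.0,
    )


def low_amplitude_preset(noise_sd: float = 8.0) -> WellSimParams:
    """Near-arrhythmic strain: tiny-amplitude ~33 h oscillation, undamped."""
    return WellSimParams(
        trend=DEFAULT_QUARTIC_TREND,
        osc_amplitude=8.0,
        period=33.3,
        phase=1.0,
        damping=0.0,
        noise_sd=noise_sd,
        transient_amplitude=40.0,
    )


def damped_preset(
    noise_sd: float = 8.0,
    period: float = 26.0,
    damping: float = 0.02,
    phase_advance_h: float = 7.0,
    relative_first_peak: float = 1.0 / 3.0,
    reference: WellSimParams | None = None,
) -> WellSimParams:
    """Damped oscillator whose FIRST PEAK is advanced by ``phase_advance_h``
    hours and scaled to ``relative_first_peak`` of the reference preset's
    first-peak height.

    Both offsets are encoded exactly at the realized extremum of the damped
    cosine: an extremum of exp(-l t) cos(w t + phi) sits where
    w t + phi = 2 pi - atan(l/w), so the phase is solved so that this
    extremum lands ``phase_advance_h`` hours before the reference's first
    cosine maximum, and A0 is solved so the realized height there equals
    ``relative_first_peak`` times the (undamped) reference amplitude.
    """
    ref = reference if reference is not None else reference_preset(noise_sd)
    w_ref = 2.0 * math.pi / ref.period
    t_peak_ref = (2.0 * math.pi - ref.phase) / w_ref  # first cosine maximum
    t_peak = t_peak_ref - phase_advance_h
    if t_peak <= 0:
        raise ParamError("phase advance puts the first peak before t = 0")
    w = 2.0 * math.pi / period
    delta = math.atan2(damping, w)  # extremum shift of the damped cosine
    phase = 2.0 * math.pi - delta - w * t_peak
    realized = math.exp(-damping * t_peak) * math.cos(w * t_peak + phase)
    target_height = relative_first_peak * ref.osc_amplitude
    return replace(
        ref,
        osc_amplitude=target_height / realized,
        period=period,
        phase=phase,
        damping=damping,
        noise_sd=noise_sd,
    )


def default_strain_presets(noise_sd: float = 8.0) -> dict[str, WellSimParams]:
    """Three-strain plate mirroring the qualitative strain classes the
    pipeline is meant to separate: a self-sustained ~26 h wild-type-like
    oscillator, a near-arrhythmic long-period strain, and a damped,
    phase-advanced, low-amplitude strain."""
    return {
        "WT": reference_preset(noise_sd),
        "dkaiA1B1C1": low_amplitude_preset(noise_sd),
        "dkaiA3B3C3": damped_preset(noise_sd),
    }


def default_experiment(seed: int = 0, noise_sd: float = 8.0, replicates: int = 5) -> ExperimentSpec:
    return ExperimentSpec(
        strains=default_strain_presets(noise_sd), replicates=replicates, seed=seed
    )
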