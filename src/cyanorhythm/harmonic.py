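"""Bounded least-squares fit of a simple harmonic oscillation.

The model is the cosinor-style single cosine

    y(t) = A * cos(omega * t + phi)

fitted to a processed (detrended, normalized, smoothed) trace under box
constraints: 0 <= A <= max(data) - mean(data), omega between 2*pi/max_period
and 2*pi/min_period, and phi in [2*pi/12, 2*pi].  The free-running period is
2*pi/omega.  The objective is multimodal in omega, so the fit multi-starts
from a grid of candidate periods and keeps the best converged solution
(smallest residual sum of squares; ties broken by smaller period).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError

TWO_PI = 2.0 * math.pi

#: Widest period envelope used for default bounds (hours).
DEFAULT_MIN_PERIOD_H = 18.0
DEFAULT_MAX_PERIOD_H = 45.0

#: Phase-angle box: 2*pi/12 <= phi <= 2*pi.
PHI_MIN = TWO_PI / 12.0
PHI_MAX = TWO_PI


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for (A, omega, phi)."""

    A_max: float
    omega_min: float
    omega_max: float
    A_min: float = 0.0
    phi_min: float = PHI_MIN
    phi_max: float = PHI_MAX

    def __post_init__(self):
        if self.A_max < self.A_min:
            raise DomainError("A_max must be >= A_min")
        if not (0 < self.omega_min <= self.omega_max):
            raise DomainError("need 0 < omega_min <= omega_max")
        if self.phi_min > self.phi_max:
            raise DomainError("phi_min must be <= phi_max")

    @property
    def min_period(self) -> float:
        return TWO_PI / self.omega_max

    @property
    def max_period(self) -> float:
        return TWO_PI / self.omega_min


@dataclass
class HarmonicFitResult:
    """Fitted (A, omega, phi), the derived period, and fit diagnostics.

    ``relative_rss`` is rss divided by the total sum of squares about the
    signal mean; callers can use it to decide that a strain is not well
    described by a single cosine (no threshold is applied here).
    """

    A: float
    omega: float
    phi: float
    period: float
    rss: float
    converged: bool
    n_points: int
    relative_rss: float
    degenerate: bool = False


def default_bounds(
    smoothed,
    min_period: float = DEFAULT_MIN_PERIOD_H,
    max_period: float = DEFAULT_MAX_PERIOD_H,
) -> FitBounds:
    """Amplitude box from the data (max - mean), frequency box from the
    period envelope, phase box [2*pi/12, 2*pi]."""
    if not (0 < min_period < max_period):
        raise DomainError("need max_period > min_period > 0")
    x = np.asarray(smoothed, dtype=float)
    a_max = float(x.max() - x.mean())
    if a_max <= 0:
        warnings.warn("constant series: amplitude bound is degenerate (A_max = 0)", stacklevel=2)
        a_max = 0.0
    return FitBounds(A_max=a_max, omega_min=TWO_PI / max_period, omega_max=TWO_PI / min_period)


def _residual(params, t, y):
    a, w, p = params
    return a * np.cos(w * t + p) - y


def _jacobian(params, t, y):
    a, w, p = params
    s = np.sin(w * t + p)
    return np.column_stack((np.cos(w * t + p), -a * t * s, -a * s))


def fit_cosine(
    times,
    smoothed,
    bounds: FitBounds,
    n_starts: int = 8,
    tolerance: float = 1e-10,
) -> HarmonicFitResult:
    """Multi-start bounded least-squares cosine fit.

    Starts are taken at ``n_starts`` equally spaced periods across the
    period box, with A at half its upper bound and phi at the middle of its
    box.  A trust-region reflective solver enforces the box; the best start
    by (rss, period) wins.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(smoothed, dtype=float)
    if t.shape != y.shape:
        raise FitError("times and values must have equal length")
    if t.size < 4:
        raise FitError("need at least 4 points for a 3-parameter fit")

    tss = float(np.sum((y - y.mean()) ** 2))
    if bounds.A_max <= 0:
        # Degenerate amplitude box: nothing to fit.
        w_mid = math.sqrt(bounds.omega_min * bounds.omega_max)
        return HarmonicFitResult(
            A=0.0, omega=w_mid, phi=0.5 * (bounds.phi_min + bounds.phi_max),
            period=TWO_PI / w_mid, rss=float(np.sum(y**2)), converged=False,
            n_points=t.size, relative_rss=1.0 if tss == 0 else float(np.sum(y**2)) / tss,
            degenerate=True,
        )

    lower = (bounds.A_min, bounds.omega_min, bounds.phi_min)
    upper = (bounds.A_max, bounds.omega_max, bounds.phi_max)
    phi0 = 0.5 * (bounds.phi_min + bounds.phi_max)
    a0 = max(bounds.A_min, min(bounds.A_max, bounds.A_max / 2.0))

    best = None
    best_key = None
    any_success = False
    for period0 in np.linspace(bounds.min_period, bounds.max_period, n_starts):
        x0 = (a0, TWO_PI / period0, phi0)
        try:
            res = least_squares(
                _residual, x0, jac=_jacobian, bounds=(lower, upper),
                args=(t, y), method="trf", xtol=tolerance, ftol=tolerance, gtol=tolerance,
            )
        except Exception:  # solver breakdown on one start is not fatal
            continue
        rss = float(2.0 * res.cost)
        period = TWO_PI / res.x[1]
        key = (rss, period)
        if best_key is None or key < best_key:
            best, best_key = res, key
            any_success = res.success or any_success
        if res.success:
            any_success = True

    if best is None:
        raise FitError("all fit starts failed", best_attempt=None)

    a, w, p = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    degenerate = a <= max(1e-12, 1e-9 * bounds.A_max)
    result = HarmonicFitResult(
        A=a, omega=w, phi=p, period=TWO_PI / w, rss=rss,
        converged=bool(best.success and not degenerate),
        n_points=t.size,
        relative_rss=(rss / tss) if tss > 0 else float("inf") if rss > 0 else 0.0,
        degenerate=degenerate,
    )
    if not any_success:
        raise FitError("no fit start converged", best_attempt=result)
    return result


def period_of(fit: HarmonicFitResult) -> float:
    """Free-running period 2*pi/omega in hours."""
    if fit.omega <= 0:
        raise DomainError("omega must be > 0")
    return TWO_PI / fit.omega
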