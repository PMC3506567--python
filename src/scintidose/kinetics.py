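"""Time-activity kinetics: mono-exponential fitting and cumulated activity.

The clinical protocol images at ~1 h, 1 d, 2 d and 7 d after infusion
onset.  Measured activities are decay-corrected, a mono-exponential
A(t) = A0 * exp(-lambda_bio * t) is fitted, and the effective decay
constant lambda_eff = lambda_bio + lambda_phys then gives the cumulated
activity (total number of decays in the organ from t = 0 to infinity):

    A_tilde = integral_0^inf A0 * exp(-lambda_eff * t) dt = A0 / lambda_eff

When the uptake is still rising over the fitted points, lambda_bio can be
negative enough that lambda_eff <= 0; the integral then diverges.  Such
fits are *unbounded* and propagate as flagged values so cohort-level code
can count and exclude them rather than crash.

The production fit is nonlinear least squares on the linear scale
(log-linear fitting would over-weight the small late values); a log-linear
fit only seeds the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import LU177_LAMBDA_PHYS

__all__ = [
    "TimeActivitySeries",
    "KineticFit",
    "CumulatedActivity",
    "decay_correct",
    "fit_monoexp",
    "cumulated_activity",
]


@dataclass(frozen=True)
class TimeActivitySeries:
    """Measured organ activities over time.

    ``times_h`` strictly increasing; ``activities_mbq`` >= 0.
    ``decay_corrected`` marks whether physical decay has been divided out.
    """

    times_h: tuple[float, ...]
    activities_mbq: tuple[float, ...]
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h)
        a = np.asarray(self.activities_mbq)
        if t.size != a.size:
            raise ValueError("times and activities differ in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("activities must be >= 0")

    @classmethod
    def from_points(
        cls, points: Sequence[tuple[float, float]], decay_corrected: bool = False
    ) -> "TimeActivitySeries":
        times, acts = zip(*points)
        return cls(tuple(float(t) for t in times), tuple(float(a) for a in acts), decay_corrected)

    def drop_time(self, time_h: float) -> "TimeActivitySeries":
        """Series without the point at ``time_h`` (exact match required)."""
        keep = [(t, a) for t, a in zip(self.times_h, self.activities_mbq) if t != time_h]
        if len(keep) == len(self.times_h):
            raise ValueError(f"no point at t = {time_h} h")
        return TimeActivitySeries.from_points(keep, self.decay_corrected)


@dataclass(frozen=True)
class KineticFit:
    """Mono-exponential fit of a decay-corrected time-activity curve."""

    a0_mbq: float
    lambda_bio: float  # h^-1; negative while uptake still rising
    lambda_phys: float  # h^-1
    r_squared: float  # linear scale
    n_points: int

    @property
    def lambda_eff(self) -> float:
        return self.lambda_bio + self.lambda_phys

    @property
    def bounded(self) -> bool:
        return self.lambda_eff > 0


@dataclass(frozen=True)
class CumulatedActivity:
    """Time-integrated activity; unbounded when lambda_eff <= 0."""

    a_tilde_mbq_h: float  # nan when unbounded
    bounded: bool

    @property
    def decays(self) -> float:
        """Number of disintegrations (1 MBq.h = 3.6e9 decays)."""
        return self.a_tilde_mbq_h * 3.6e9


def decay_correct(series: TimeActivitySeries, lambda_phys: float = LU177_LAMBDA_PHYS) -> TimeActivitySeries:
    """Divide out physical decay: A(t) -> A(t) * exp(+lambda_phys * t)."""
    if series.decay_corrected:
        raise ValueError("series is already decay-corrected")
    acts = tuple(
        a * float(np.exp(lambda_phys * t)) for t, a in zip(series.times_h, series.activities_mbq)
    )
    return replace(series, activities_mbq=acts, decay_corrected=True)


def fit_monoexp(
    series: TimeActivitySeries, lambda_phys: float = LU177_LAMBDA_PHYS
) -> KineticFit:
    """Fit A(t) = A0 * exp(-lambda_bio * t) to a decay-corrected series.

    Nonlinear least squares on the linear scale, initialized from the
    log-linear regression over the positive points.  R^2 is computed on the
    linear scale.  Requires >= 2 points with positive activity.
    """
    t = np.asarray(series.times_h, dtype=float)
    a = np.asarray(series.activities_mbq, dtype=float)
    pos = a > 0
    if pos.sum() < 2:
        raise ValueError("need >= 2 points with positive activity")

    # log-linear seed on the positive subset
    coef = np.polyfit(t[pos], np.log(a[pos]), 1)
    lam0, loga0 = -coef[0], coef[1]
    p0 = [float(np.exp(loga0)), float(lam0)]

    def model(tt, a0, lam):
        return a0 * np.exp(-lam * tt)

    try:
        popt, _ = curve_fit(model, t, a, p0=p0, maxfev=10000)
        a0_hat, lam_hat = float(popt[0]), float(popt[1])
    except RuntimeError:
        a0_hat, lam_hat = p0  # fall back to the log-linear estimate

    resid = a - model(t, a0_hat, lam_hat)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return KineticFit(
        a0_mbq=a0_hat,
        lambda_bio=lam_hat,
        lambda_phys=lambda_phys,
        r_squared=r2,
        n_points=int(t.size),
    )


def cumulated_activity(fit: KineticFit) -> CumulatedActivity:
    """A_tilde = A0 / lambda_eff; flagged unbounded when lambda_eff <= 0."""
    if not fit.bounded:
        return CumulatedActivity(a_tilde_mbq_h=float("nan"), bounded=False)
    return CumulatedActivity(a_tilde_mbq_h=fit.a0_mbq / fit.lambda_eff, bounded=True)
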