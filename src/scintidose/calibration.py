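"""Gamma-camera calibration from a depth-count series.

A small source of known activity is imaged at increasing depths in an
attenuating phantom; the count rate follows rate(d) = k * A * exp(-mu*d).
Fitting that curve gives the camera sensitivity ``k`` (the extrapolated
intercept at zero depth divided by the source activity) and the effective
linear attenuation coefficient ``mu`` (the exponential constant).

The model is exactly linearizable, so the fit is ordinary least squares of
log-rate on depth (unweighted; calibration counts are large, so log-domain
heteroscedasticity is negligible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CalibrationResult", "fit_depth_series"]


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted camera sensitivity and effective attenuation coefficient."""

    sensitivity_k: float  # cps/MBq
    mu: float  # cm^-1
    fit_r_squared: float  # on the log scale
    n_points: int

    def __post_init__(self) -> None:
        if self.sensitivity_k <= 0:
            raise ValueError("sensitivity_k must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


def fit_depth_series(series: pd.DataFrame, source_activity: float) -> CalibrationResult:
    """Estimate (k, mu) from a ``depth_cm, counts, duration_s`` table.

    Least squares on log(rate) vs depth: ``mu`` is minus the slope, ``k``
    is exp(intercept) / A.  Requires >= 3 distinct depths and strictly
    positive counts (the log is undefined otherwise).  A depth-independent
    series returns ``mu = 0`` exactly.
    """
    if source_activity <= 0:
        raise ValueError("source_activity must be positive")
    depth = np.asarray(series["depth_cm"], dtype=float)
    counts = np.asarray(series["counts"], dtype=float)
    duration = np.asarray(series["duration_s"], dtype=float)
    if np.unique(depth).size < 3:
        raise ValueError("need at least 3 distinct depths")
    if np.any(counts <= 0):
        raise ValueError("all counts must be positive for the log-linear fit")
    log_rate = np.log(counts / duration)
    res = stats.linregress(depth, log_rate)
    mu = -res.slope
    if abs(mu) < 1e-15:
        mu = 0.0
    if mu < 0:
        # a rising series is not attenuation; surface it rather than clamp
        raise ValueError(f"fitted attenuation coefficient is negative ({mu:.3g} cm^-1)")
    k = float(np.exp(res.intercept)) / source_activity
    return CalibrationResult(
        sensitivity_k=k,
        mu=float(mu),
        fit_r_squared=float(res.rvalue**2),
        n_points=int(depth.size),
    )
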