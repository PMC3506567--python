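"""Kidney activity quantification from planar images.

Implements the two planar estimators used for 177Lu-octreotate kidney
dosimetry:

* the conjugate-view (CV) method — geometric mean of the background-
  corrected anterior and posterior ROI count rates, corrected for body
  attenuation and source self-attenuation:

      A = sqrt(R_A * R_P) * exp(mu*T/2) * mu*x
          / (k * (exp(mu*x/2) - exp(-mu*x/2)))

  Depth-independent for a uniform slab source: the kidney's AP position
  cancels in the geometric mean.

* the posterior-only (PA) method — requires the kidney's posterior depth
  ``a`` and corrects attenuation explicitly:

      A = R_P * exp(mu*a) * mu*x / (k * (1 - exp(-mu*x)))

Both exactly invert the noiseless slab forward model (see
:mod:`scintidose.phantom`); any error in the assumed depth ``a`` biases the
PA estimate by the factor exp(mu*delta_a).

Supporting steps: ROI count-rate extraction, ROI mirroring between
posterior and anterior views, extrapolation of partial-kidney ROIs (used
when overlapping uptake hides part of the kidney), and background
subtraction scaled to the body thickness minus the kidney thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .calibration import CalibrationResult
from .phantom import CountImage, RateImage

__all__ = [
    "RoiMask",
    "RoiCounts",
    "ActivityEstimate",
    "roi_rate",
    "mirror_roi",
    "extrapolate_partial",
    "background_correct",
    "cv_thickness_factor",
    "activity_cv",
    "activity_pa",
]


@dataclass(frozen=True)
class RoiMask:
    """A set of (row, col) pixels with a label and role."""

    pixels: frozenset[tuple[int, int]]
    label: str = ""
    kind: Literal["kidney", "background", "partial-kidney"] = "kidney"

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError(f"ROI {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.pixels)

    @classmethod
    def from_pixels(
        cls,
        pixels: Iterable[tuple[int, int]],
        label: str = "",
        kind: Literal["kidney", "background", "partial-kidney"] = "kidney",
    ) -> "RoiMask":
        return cls(pixels=frozenset((int(r), int(c)) for r, c in pixels), label=label, kind=kind)


@dataclass(frozen=True)
class RoiCounts:
    """Background-corrected anterior/posterior count rates for one kidney."""

    rate_anterior: float  # cps
    rate_posterior: float  # cps
    n_pixels_total: int
    n_pixels_used: int
    clamped: bool = False  # True if a negative corrected rate was clamped to 0


@dataclass(frozen=True)
class ActivityEstimate:
    """Kidney activity from one planar method at one time point."""

    activity: float  # MBq
    method: Literal["CV", "PA"]
    time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be >= 0")


def _check_bounds(roi: RoiMask, shape: tuple[int, int]) -> None:
    rows, cols = shape
    for r, c in roi.pixels:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"ROI {roi.label!r}: pixel ({r}, {c}) outside {rows}x{cols} image")


def roi_rate(image: CountImage | RateImage, roi: RoiMask) -> tuple[float, float]:
    """(total cps, mean cps/pixel) over an ROI.

    Count images are converted to rates with the dwell time; rate images
    are summed directly.
    """
    _check_bounds(roi, image.pixels.shape)
    idx = np.array(sorted(roi.pixels))
    total = float(image.pixels[idx[:, 0], idx[:, 1]].sum())
    if isinstance(image, CountImage):
        total /= image.dwell_time
    return total, total / len(roi)


def mirror_roi(roi: RoiMask, image_cols: int) -> RoiMask:
    """Mirror an ROI left-right for use on the opposite view (c -> cols-1-c)."""
    return RoiMask(
        pixels=frozenset((r, image_cols - 1 - c) for r, c in roi.pixels),
        label=roi.label,
        kind=roi.kind,
    )


def extrapolate_partial(rate_partial: float, n_partial: int, n_total: int) -> float:
    """Scale a partial-kidney ROI rate to the whole kidney.

    Assumes uniform counts per pixel over the kidney, as when part of the
    kidney is obscured by overlapping uptake and only a clean sub-ROI is
    usable.
    """
    if n_partial < 1:
        raise ValueError("n_partial must be >= 1")
    if n_total < n_partial:
        raise ValueError("n_total must be >= n_partial")
    return rate_partial * n_total / n_partial


def background_correct(
    kidney_mean_cpp: float,
    bg_mean_cpp: float,
    trunk_thickness_T: float,
    kidney_thickness_x: float,
    n_kidney_pixels: int,
) -> tuple[float, bool]:
    """Background-subtracted total kidney count rate.

    The background ROI samples the full body thickness ``T``; behind and in
    front of the kidney only ``T - x`` of background tissue remains, so the
    background per-pixel rate is scaled by ``(T - x)/T`` before
    subtraction.  Negative corrected rates are clamped to zero and flagged.

    Returns (corrected total cps, clamped flag).
    """
    if not 0 <= kidney_thickness_x <= trunk_thickness_T:
        raise ValueError("kidney thickness must satisfy 0 <= x <= T")
    per_pixel = kidney_mean_cpp - bg_mean_cpp * (trunk_thickness_T - kidney_thickness_x) / trunk_thickness_T
    clamped = per_pixel < 0
    return max(per_pixel, 0.0) * n_kidney_pixels, clamped


def cv_thickness_factor(mu: float, x: float) -> float:
    """Source self-attenuation factor mu*x / (2*sinh(mu*x/2)); -> 1 as x -> 0."""
    ux = mu * x
    if ux == 0:
        return 1.0
    return ux / (2.0 * math.sinh(ux / 2.0))


def activity_cv(
    rate_anterior: float,
    rate_posterior: float,
    trunk_thickness_T: float,
    kidney_thickness_x: float,
    calib: CalibrationResult,
    time_h: float = 0.0,
) -> ActivityEstimate:
    """Conjugate-view activity estimate (MBq)."""
    if rate_anterior < 0 or rate_posterior < 0:
        raise ValueError("count rates must be >= 0")
    if kidney_thickness_x < 0:
        raise ValueError("kidney thickness must be >= 0")
    if kidney_thickness_x > trunk_thickness_T:
        raise ValueError("kidney thickness exceeds body thickness")
    geo_mean = math.sqrt(rate_anterior * rate_posterior)
    a = (
        geo_mean
        * math.exp(calib.mu * trunk_thickness_T / 2.0)
        * cv_thickness_factor(calib.mu, kidney_thickness_x)
        / calib.sensitivity_k
    )
    return ActivityEstimate(activity=a, method="CV", time_h=time_h)


def activity_pa(
    rate_posterior: float,
    depth_a: float,
    kidney_thickness_x: float,
    calib: CalibrationResult,
    time_h: float = 0.0,
) -> ActivityEstimate:
    """Posterior-only activity estimate (MBq); needs the kidney depth ``a``."""
    if rate_posterior < 0:
        raise ValueError("count rate must be >= 0")
    if depth_a < 0:
        raise ValueError("depth_a must be >= 0")
    if kidney_thickness_x < 0:
        raise ValueError("kidney thickness must be >= 0")
    ux = calib.mu * kidney_thickness_x
    if ux == 0:
        self_atten = 1.0
    else:
        self_atten = ux / (1.0 - math.exp(-ux))
    a = rate_posterior * math.exp(calib.mu * depth_a) * self_atten / calib.sensitivity_k
    return ActivityEstimate(activity=a, method="PA", time_h=time_h)
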