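"""Synthetic planar-scintigraphy phantom.

Forward-projects a slab-body digital phantom with embedded uniform-activity
sources into anterior/posterior planar count-rate images under exponential
photon attenuation, adds Poisson counting noise, and generates the two input
series the quantification pipeline consumes: calibration depth-count series
and multi-time-point patient image series.

Geometry convention
-------------------
The body is a homogeneous slab of anterior-posterior thickness ``T`` (cm).
Each source region occupies a set of image pixels (its *footprint*) and an
AP extent ``x`` starting at distance ``a`` from the posterior surface
(``a`` is measured to the *posterior* edge of the region).  The posterior
camera looks through ``a`` cm of tissue before reaching the source; the
anterior camera through ``T - a - x`` cm.  Anterior images are left-right
mirrored relative to posterior images, as on a real gantry.

For a uniform slab source of thickness ``x`` viewed through ``d`` cm of
overlying tissue, the detected rate integrates the exponential attenuation
over the source depth:

    R = k * A * exp(-mu*d) * (1 - exp(-mu*x)) / (mu*x)

which is what the conjugate-view and posterior-only estimators invert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import LU177_LAMBDA_PHYS

View = Literal["anterior", "posterior"]

__all__ = [
    "CameraModel",
    "SourceRegion",
    "PhantomSpec",
    "RateImage",
    "CountImage",
    "ellipsoid_footprint",
    "build_projection",
    "sample_counts",
    "make_calibration_series",
    "monoexp_kinetics",
    "biphasic_kinetics",
    "make_patient_series",
]


@dataclass(frozen=True)
class CameraModel:
    """Gamma-camera response: sensitivity, effective attenuation, dwell time.

    Parameters
    ----------
    sensitivity_k : float
        Count rate per unit unattenuated activity, cps/MBq.
    mu : float
        Effective (broad-beam) linear attenuation coefficient, cm^-1.
        Absorbs scatter for the camera/energy-window combination.
    dwell_time : float
        Effective acquisition time per pixel, s.  Whole-body scans are
        modeled as static images with this dwell time.
    """

    sensitivity_k: float
    mu: float
    dwell_time: float = 1.0

    def __post_init__(self) -> None:
        if self.sensitivity_k <= 0:
            raise ValueError("sensitivity_k must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")


@dataclass(frozen=True)
class SourceRegion:
    """A uniform-activity source inside the slab body.

    ``footprint`` is the set of (row, col) pixels the region projects onto.
    ``thickness_x`` is the AP extent in cm (for an ellipsoid, the maximum
    AP chord); ``depth_a`` is the distance from the posterior body surface
    to the posterior edge of the region.  ``activity`` (MBq) is distributed
    uniformly over the region's volume.

    For ``shape="ellipsoid"`` the in-plane semi-axes and center must be
    given in cm (pixel-center physical coordinates); the AP chord then
    varies per pixel and the footprint should come from
    :func:`ellipsoid_footprint`.
    """

    label: str
    footprint: frozenset[tuple[int, int]]
    thickness_x: float
    depth_a: float
    activity: float
    shape: Literal["box", "ellipsoid"] = "box"
    center_cm: tuple[float, float] | None = None  # (row_cm, col_cm), ellipsoid only
    semi_axes_cm: tuple[float, float] | None = None  # in-plane (row, col) semi-axes

    def __post_init__(self) -> None:
        if not self.footprint:
            raise ValueError(f"source {self.label!r}: footprint is empty")
        if self.thickness_x <= 0:
            raise ValueError(f"source {self.label!r}: thickness_x must be positive")
        if self.activity < 0:
            raise ValueError(f"source {self.label!r}: activity must be >= 0")
        if self.depth_a < 0:
            raise ValueError(f"source {self.label!r}: depth_a must be >= 0")
        if self.shape == "ellipsoid" and (self.center_cm is None or self.semi_axes_cm is None):
            raise ValueError(f"source {self.label!r}: ellipsoid needs center_cm and semi_axes_cm")


@dataclass(frozen=True)
class PhantomSpec:
    """Digital slab-body phantom: geometry, sources, and camera."""

    trunk_thickness_T: float
    pixel_size: float
    grid_rows: int
    grid_cols: int
    compartments: tuple[SourceRegion, ...]
    camera: CameraModel

    def __post_init__(self) -> None:
        if self.trunk_thickness_T <= 0:
            raise ValueError("trunk_thickness_T must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for c in self.compartments:
            if c.depth_a + c.thickness_x > self.trunk_thickness_T + 1e-12:
                raise ValueError(
                    f"compartment {c.label!r} extends outside the slab: "
                    f"depth_a + thickness_x = {c.depth_a + c.thickness_x:.3f} cm "
                    f"> T = {self.trunk_thickness_T:.3f} cm"
                )
            for r, col in c.footprint:
                if not (0 <= r < self.grid_rows and 0 <= col < self.grid_cols):
                    raise ValueError(
                        f"compartment {c.label!r}: pixel ({r}, {col}) outside "
                        f"{self.grid_rows}x{self.grid_cols} grid"
                    )

    def with_activities(self, activities: dict[str, float]) -> "PhantomSpec":
        """Return a copy with per-label activities replaced."""
        comps = tuple(
            replace(c, activity=activities.get(c.label, c.activity))
            for c in self.compartments
        )
        return replace(self, compartments=comps)


@dataclass(frozen=True)
class RateImage:
    """Noiseless planar count-rate image (cps per pixel)."""

    pixels: np.ndarray
    view: View
    pixel_size: float
    dwell_time: float
    acquisition_time_h: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.pixels < 0):
            raise ValueError("rate image has negative pixels")


@dataclass(frozen=True)
class CountImage:
    """Planar image of integer counts."""

    pixels: np.ndarray
    view: View
    pixel_size: float
    dwell_time: float
    acquisition_time_h: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.pixels < 0):
            raise ValueError("count image has negative pixels")


def ellipsoid_footprint(
    center_rc: tuple[int, int],
    semi_axes_px: tuple[float, float],
    grid: tuple[int, int],
) -> frozenset[tuple[int, int]]:
    """Pixels whose centers fall inside an in-plane ellipse.

    ``center_rc`` in pixel indices, ``semi_axes_px`` in pixels.
    """
    rows, cols = grid
    rr, cc = np.mgrid[0:rows, 0:cols]
    u = (rr - center_rc[0]) / semi_axes_px[0]
    v = (cc - center_rc[1]) / semi_axes_px[1]
    inside = u * u + v * v < 1.0
    return frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(inside)))


def _region_chords(spec: PhantomSpec, region: SourceRegion) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-footprint-pixel (rows, cols, AP chord in cm).

    Box regions have a constant chord; ellipsoids an elliptic chord computed
    analytically at each pixel center (no sub-pixel integration).
    """
    idx = np.array(sorted(region.footprint))
    rows, cols = idx[:, 0], idx[:, 1]
    if region.shape == "box":
        chord = np.full(len(rows), region.thickness_x)
        return rows, cols, chord
    # ellipsoid: chord(r,c) = x * sqrt(1 - u^2 - v^2) at pixel centers
    pr = (rows + 0.5) * spec.pixel_size
    pc = (cols + 0.5) * spec.pixel_size
    cr, ccm = region.center_cm
    sr, sc = region.semi_axes_cm
    q = 1.0 - ((pr - cr) / sr) ** 2 - ((pc - ccm) / sc) ** 2
    chord = region.thickness_x * np.sqrt(np.clip(q, 0.0, None))
    keep = chord > 0
    return rows[keep], cols[keep], chord[keep]


def _region_volume(spec: PhantomSpec, region: SourceRegion) -> float:
    rows, cols, chord = _region_chords(spec, region)
    return float(chord.sum()) * spec.pixel_size**2


def build_projection(spec: PhantomSpec, view: View) -> RateImage:
    """Forward-project the phantom into a planar count-rate image.

    Each pixel covered by a compartment receives

        rate = k * rho * [exp(-mu*d_near) - exp(-mu*(d_near + x_pix))] / mu
               * pixel_area

    with ``rho`` the volumetric activity concentration (MBq/cm^3), ``x_pix``
    the AP chord at the pixel, and ``d_near`` the tissue thickness between
    the detector-side body surface and the near edge of the compartment
    (posterior view: ``depth_a``; anterior view: ``T - depth_a - x_pix``).
    Contributions are additive across compartments.  Anterior images are
    left-right mirrored.  ``mu = 0`` degenerates to ``k * rho * x_pix *
    pixel_area``.
    """
    if view not in ("anterior", "posterior"):
        raise ValueError(f"unknown view {view!r}")
    cam = spec.camera
    img = np.zeros((spec.grid_rows, spec.grid_cols))
    area = spec.pixel_size**2
    for region in spec.compartments:
        if region.activity == 0:
            continue
        rows, cols, chord = _region_chords(spec, region)
        volume = float(chord.sum()) * area
        rho = region.activity / volume
        if region.shape == "box":
            d_near = np.full_like(chord, region.depth_a)
        else:
            # chord is centered on the region's AP mid-plane
            mid = region.depth_a + region.thickness_x / 2.0
            d_near = mid - chord / 2.0
        if view == "anterior":
            d_near = spec.trunk_thickness_T - d_near - chord
        if cam.mu > 0:
            atten = (np.exp(-cam.mu * d_near) - np.exp(-cam.mu * (d_near + chord))) / cam.mu
        else:
            atten = chord
        np.add.at(img, (rows, cols), cam.sensitivity_k * rho * atten * area)
    if view == "anterior":
        img = img[:, ::-1]
    return RateImage(
        pixels=img, view=view, pixel_size=spec.pixel_size, dwell_time=cam.dwell_time
    )


def sample_counts(rate: RateImage, seed: int) -> CountImage:
    """Poisson-sample a rate image into integer counts (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    mean = rate.pixels * rate.dwell_time
    counts = rng.poisson(mean)
    return CountImage(
        pixels=counts,
        view=rate.view,
        pixel_size=rate.pixel_size,
        dwell_time=rate.dwell_time,
        acquisition_time_h=rate.acquisition_time_h,
    )


def make_calibration_series(
    camera: CameraModel,
    depths: Sequence[float],
    source_activity: float,
    duration: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Depth-count series from a point-like source in a slab phantom.

    Emulates imaging a small source at successive depths in an attenuating
    phantom: noiseless counts(d) = k * A * exp(-mu*d) * duration.  With a
    seed, counts are Poisson-sampled.  Returns columns
    ``depth_cm, counts, duration_s``.
    """
    depths = np.asarray(list(depths), dtype=float)
    if depths.size == 0:
        raise ValueError("depth list is empty")
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    if source_activity < 0:
        raise ValueError("source_activity must be >= 0")
    mean_counts = camera.sensitivity_k * source_activity * np.exp(-camera.mu * depths) * duration
    if seed is None:
        counts = mean_counts
    else:
        counts = np.random.default_rng(seed).poisson(mean_counts).astype(float)
    return pd.DataFrame(
        {"depth_cm": depths, "counts": counts, "duration_s": duration}
    )


def monoexp_kinetics(a0: float, lambda_bio: float) -> Callable[[float], float]:
    """Decay-corrected mono-exponential retention A0*exp(-lambda_bio*t)."""
    if a0 <= 0:
        raise ValueError("A0 must be positive")
    return lambda t: a0 * np.exp(-lambda_bio * t)


def biexp_kinetics(
    a0: float, frac_fast: float, lambda_fast: float, lambda_slow: float
) -> Callable[[float], float]:
    """Fast-then-slow clearance A0*(f*exp(-l_fast*t) + (1-f)*exp(-l_slow*t)).

    The typical kidney retention pattern: a rapid early washout followed by
    a slower terminal phase.  Peaks at t = 0.
    """
    if a0 <= 0:
        raise ValueError("A0 must be positive")
    if not 0 <= frac_fast <= 1:
        raise ValueError("frac_fast must be in [0, 1]")
    return lambda t: a0 * (
        frac_fast * np.exp(-lambda_fast * t) + (1 - frac_fast) * np.exp(-lambda_slow * t)
    )


def biphasic_kinetics(a0: float, lambda_clear: float, lambda_uptake: float) -> Callable[[float], float]:
    """Uptake-then-clearance retention A0*(exp(-l_clear*t) - exp(-l_uptake*t)).

    Peaks after t=0 whenever ``lambda_uptake > lambda_clear``; emulates the
    patients whose kidney uptake rises through day 1-2.
    """
    if a0 <= 0:
        raise ValueError("A0 must be positive")
    if lambda_uptake <= lambda_clear:
        raise ValueError("lambda_uptake must exceed lambda_clear for an uptake phase")
    return lambda t: a0 * (np.exp(-lambda_clear * t) - np.exp(-lambda_uptake * t))


def make_patient_series(
    spec: PhantomSpec,
    kinetics: dict[str, Callable[[float], float]],
    times_h: Sequence[float],
    seed: int,
    lambda_phys: float = LU177_LAMBDA_PHYS,
    background_kinetics: Callable[[float], float] | None = None,
    noiseless: bool = False,
) -> list[tuple[CountImage | RateImage, CountImage | RateImage, float]]:
    """Simulate a multi-time-point anterior/posterior imaging series.

    ``kinetics`` maps compartment labels to *decay-corrected* retention
    functions of time (h) giving the compartment activity in MBq; the
    imaged activity additionally decays physically, i.e.
    A_imaged(t) = kinetics(t) * exp(-lambda_phys*t).  Compartments without
    an entry keep their static activity, scaled by the dimensionless
    ``background_kinetics(t)`` retention factor if one is given (so a
    multi-compartment background keeps its volume-proportional split);
    physical decay applies to those too.

    Returns a list of (anterior, posterior, time_h) with Poisson-sampled
    counts, or noiseless rate images if ``noiseless``.
    """
    times = np.asarray(list(times_h), dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("need >= 2 strictly increasing time points")
    out = []
    rng = np.random.default_rng(seed)
    for t in times:
        phys = np.exp(-lambda_phys * t)
        acts = {}
        for c in spec.compartments:
            if c.label in kinetics:
                acts[c.label] = float(kinetics[c.label](t)) * phys
            elif background_kinetics is not None:
                acts[c.label] = c.activity * float(background_kinetics(t)) * phys
            else:
                acts[c.label] = c.activity * phys
        snap = spec.with_activities(acts)
        ant = build_projection(snap, "anterior")
        post = build_projection(snap, "posterior")
        ant = replace(ant, acquisition_time_h=float(t))
        post = replace(post, acquisition_time_h=float(t))
        if not noiseless:
            ant = sample_counts(ant, int(rng.integers(0, 2**31 - 1)))
            post = sample_counts(post, int(rng.integers(0, 2**31 - 1)))
        out.append((ant, post, float(t)))
    return out
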