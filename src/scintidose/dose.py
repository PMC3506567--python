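"""Mean absorbed kidney dose from cumulated activity (MIRD-style).

For 177Lu the electron energy (mean 147 keV per decay) is absorbed locally
(absorbed fraction phi = 1 for kidney-sized organs), so the self-dose is

    D [Gy] = A_tilde [decays] * nE [J/decay] * phi / m [kg]

The photon cross-dose from the rest of the body is added as a single
whole-body-to-kidney S-value term on the remainder cumulated activity.

Kidney masses come either from patient-specific CT ellipsoid estimates
(density 1.05 g/cm^3) or from reference standard sizes (ICRP 89 masses,
MIRD-5 body dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .constants import (
    KEV_TO_J,
    LU177_ELECTRON_ENERGY_KEV,
    LU177_LAMBDA_PHYS,
    MBQ_H_TO_DECAYS,
    TISSUE_DENSITY_G_CM3,
)
from .kinetics import CumulatedActivity

__all__ = [
    "GeometryRecord",
    "DoseConstants",
    "DoseResult",
    "ellipsoid_mass",
    "mean_dose",
    "remainder_dose",
    "standard_geometry",
]

_PI_OVER_6 = 0.5235987755982988


@dataclass(frozen=True)
class GeometryRecord:
    """Per-kidney geometry used for quantification and dose."""

    kidney_thickness_x: float  # cm, AP extent
    trunk_thickness_T: float  # cm
    mass_kg: float
    kidney_length_L: float | None = None  # cm
    kidney_width_W: float | None = None  # cm
    depth_a: float | None = None  # cm, posterior depth (PA method only)
    density: float = TISSUE_DENSITY_G_CM3
    sex: Literal["male", "female"] | None = None

    def __post_init__(self) -> None:
        if self.kidney_thickness_x <= 0 or self.trunk_thickness_T <= 0:
            raise ValueError("thicknesses must be positive")
        if self.kidney_thickness_x > self.trunk_thickness_T:
            raise ValueError("kidney thickness exceeds trunk thickness")
        if self.mass_kg <= 0:
            raise ValueError("mass must be positive")


@dataclass(frozen=True)
class DoseConstants:
    """Physical constants of the dose calculation."""

    energy_per_decay_kev: float = LU177_ELECTRON_ENERGY_KEV
    absorbed_fraction_phi: float = 1.0
    lambda_phys: float = LU177_LAMBDA_PHYS
    s_value_wb_to_kidney: float | None = None  # mGy/(MBq.h), user-supplied

    def __post_init__(self) -> None:
        if self.energy_per_decay_kev <= 0:
            raise ValueError("energy per decay must be positive")
        if not 0 < self.absorbed_fraction_phi <= 1:
            raise ValueError("absorbed fraction must be in (0, 1]")


@dataclass(frozen=True)
class DoseResult:
    """Mean absorbed dose to one kidney for one treatment cycle."""

    dose_gy: float  # nan when unbounded
    bounded: bool
    dose_per_admin_gy_per_gbq: float | None = None
    remainder_gy: float | None = None


def ellipsoid_mass(
    length_l: float, width_w: float, thickness_x: float, density: float = TISSUE_DENSITY_G_CM3
) -> float:
    """Kidney mass (kg) from ellipsoid axes (cm): (pi/6) L W x rho / 1000."""
    if length_l <= 0 or width_w <= 0 or thickness_x <= 0:
        raise ValueError("ellipsoid axes must be positive")
    return _PI_OVER_6 * length_l * width_w * thickness_x * density / 1000.0


def mean_dose(
    a_tilde: CumulatedActivity,
    mass_kg: float,
    constants: DoseConstants = DoseConstants(),
    administered_gbq: float | None = None,
    remainder_gy: float | None = None,
) -> DoseResult:
    """Mean absorbed dose D = A_tilde * nE * phi / m.

    Unbounded cumulated activity propagates as an unbounded dose.  When the
    administered activity is supplied, D/A_administered (Gy/GBq) is also
    reported.  ``remainder_gy`` (cross-dose from the rest of the body) is
    added to the self-dose when given.
    """
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    if not a_tilde.bounded:
        return DoseResult(dose_gy=float("nan"), bounded=False)
    energy_j = constants.energy_per_decay_kev * KEV_TO_J
    dose = a_tilde.decays * energy_j * constants.absorbed_fraction_phi / mass_kg
    if remainder_gy is not None:
        dose += remainder_gy
    per_admin = dose / administered_gbq if administered_gbq else None
    return DoseResult(
        dose_gy=dose,
        bounded=True,
        dose_per_admin_gy_per_gbq=per_admin,
        remainder_gy=remainder_gy,
    )


def remainder_dose(
    a_tilde_wb_mbq_h: float, a_tilde_kidneys_mbq_h: float, s_value_mgy_per_mbq_h: float
) -> float:
    """Cross-dose (Gy) to kidney from the remainder of the body.

    The whole-body cumulated activity minus the renal cumulated activity is
    assumed uniformly distributed and converted with a whole-body-to-kidney
    S value.
    """
    if a_tilde_wb_mbq_h < a_tilde_kidneys_mbq_h:
        raise ValueError("whole-body cumulated activity below renal cumulated activity")
    return (a_tilde_wb_mbq_h - a_tilde_kidneys_mbq_h) * s_value_mgy_per_mbq_h * 1e-3


def standard_geometry(sex: str) -> GeometryRecord:
    """Reference geometry: ICRP 89 kidney masses (310 g both kidneys for
    men, 275 g for women; halved per kidney) and MIRD-5 body dimensions
    (20 cm trunk / 6 cm kidney AP thickness for men; 18 / 5 cm for women).
    """
    if sex in ("male", "M", "m"):
        return GeometryRecord(
            kidney_thickness_x=6.0, trunk_thickness_T=20.0, mass_kg=0.155, sex="male"
        )
    if sex in ("female", "F", "f"):
        return GeometryRecord(
            kidney_thickness_x=5.0, trunk_thickness_T=18.0, mass_kg=0.1375, sex="female"
        )
    raise ValueError(f"unknown sex label {sex!r}")
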