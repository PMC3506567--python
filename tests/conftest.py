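import numpy as np
import pytest

from scintidose.calibration import CalibrationResult
from scintidose.phantom import CameraModel, PhantomSpec, SourceRegion

TRUE_K = 10.9  # cps/MBq
TRUE_MU = 0.119  # cm^-1


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel(sensitivity_k=TRUE_K, mu=TRUE_MU, dwell_time=1.0)


@pytest.fixture
def calib_truth() -> CalibrationResult:
    """Calibration carrying the exact camera parameters (no fit error)."""
    return CalibrationResult(sensitivity_k=TRUE_K, mu=TRUE_MU, fit_r_squared=1.0, n_points=0)


def box_phantom(
    camera: CameraModel,
    activity: float = 100.0,
    thickness_x: float = 6.0,
    depth_a: float = 4.0,
    trunk_T: float = 20.0,
    grid: tuple[int, int] = (32, 32),
) -> PhantomSpec:
    """Single box kidney, zero background."""
    footprint = frozenset((r, c) for r in range(10, 20) for c in range(10, 15))
    region = SourceRegion(
        label="kidney", footprint=footprint, thickness_x=thickness_x,
        depth_a=depth_a, activity=activity,
    )
    return PhantomSpec(
        trunk_thickness_T=trunk_T, pixel_size=1.0, grid_rows=grid[0], grid_cols=grid[1],
        compartments=(region,), camera=camera,
    )


@pytest.fixture
def phantom(camera) -> PhantomSpec:
    return box_phantom(camera)
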