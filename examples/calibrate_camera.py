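"""Camera calibration: recover sensitivity k and attenuation mu from a depth series.

A 330 MBq source is imaged for 300 s at depths 0.5-19 cm in an attenuating
phantom; count rate falls as k*A*exp(-mu*d).  The log-linear fit returns the
sensitivity (intercept) and effective attenuation coefficient (slope).
"""

import numpy as np

from scintidose import fit_depth_series
from scintidose.phantom import CameraModel, make_calibration_series

camera = CameraModel(sensitivity_k=10.9, mu=0.119, dwell_time=300.0)
depths = np.arange(0.5, 19.01, 0.5)

series = make_calibration_series(camera, depths, source_activity=330.0, duration=300.0, seed=1)
result = fit_depth_series(series, source_activity=330.0)

print(f"true k = {camera.sensitivity_k} cps/MBq, true mu = {camera.mu} /cm")
print(f"fitted k = {result.sensitivity_k:.3f} cps/MBq")
print(f"fitted mu = {result.mu:.4f} /cm")
print(f"R^2 (log scale) = {result.fit_r_squared:.5f} over {result.n_points} depths")
# The fitted values agree with truth to well under a percent: with Poisson
# noise at these count levels the calibration is essentially exact.
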