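"""Physical constants for 177Lu dosimetry.

All half-lives in hours, energies in keV, doses in Gy unless stated.
"""

import math

#: Physical half-life of 177Lu in days (configurable downstream).
LU177_HALF_LIFE_DAYS: float = 6.647

#: Physical half-life of 177Lu in hours.
LU177_HALF_LIFE_H: float = LU177_HALF_LIFE_DAYS * 24.0

#: Physical decay constant of 177Lu, h^-1.
LU177_LAMBDA_PHYS: float = math.log(2.0) / LU177_HALF_LIFE_H

#: Mean energy emitted by electrons per decay of 177Lu, keV.
LU177_ELECTRON_ENERGY_KEV: float = 147.0

#: 1 keV in joules.
KEV_TO_J: float = 1.602177e-19 * 1e3  # J/eV times eV/keV

#: MBq.h expressed as number of decays (1 MBq = 1e6/s, 1 h = 3600 s).
MBQ_H_TO_DECAYS: float = 3.6e9

#: Soft-tissue density used for ellipsoid kidney masses, g/cm^3.
TISSUE_DENSITY_G_CM3: float = 1.05
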