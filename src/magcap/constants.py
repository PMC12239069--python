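"""Physical constants and default material properties (SI units)."""

import math

#: Vacuum permeability, T·m/A.
MU_0 = 4.0 * math.pi * 1e-7

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: Magnetite (Fe3O4) density, kg/m^3.
MAGNETITE_DENSITY = 5180.0

#: Cross-linked PDMS density, kg/m^3.
PDMS_DENSITY = 965.0

#: Dynamic viscosity of water at 25 C, Pa·s.
WATER_VISCOSITY = 8.9e-4

#: Volume susceptibility of water. Its true value (-9e-6) is negligible at
#: the precision of the transport model, so the default is 0.
WATER_SUSCEPTIBILITY = 0.0

#: Density of water at 25 C, kg/m^3.
WATER_DENSITY = 997.0

#: Saturation magnetization of magnetite, A/m (bulk value, used only by the
#: optional Langevin susceptibility model).
MAGNETITE_SATURATION_MAGNETIZATION = 4.8e5

#: Demagnetization factor of a uniformly magnetized sphere.
SPHERE_DEMAG_FACTOR = 1.0 / 3.0
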