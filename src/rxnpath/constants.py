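"""Physical constants and unit conversions used across the package.

Internal units: energy in Hartree, length in Å, mass in amu.
"""

import math

HARTREE_TO_KCALMOL = 627.509

# SI values
_HARTREE_J = 4.3597447222071e-18
_AMU_KG = 1.66053906660e-27
_ANGSTROM_M = 1.0e-10
_C_CM_S = 2.99792458e10

# sqrt(Hartree / (amu Å^2)) -> angular frequency in s^-1, then to wavenumbers.
_OMEGA = math.sqrt(_HARTREE_J / (_AMU_KG * _ANGSTROM_M**2))
FREQ_AU_TO_CM = _OMEGA / (2.0 * math.pi * _C_CM_S)

#: Golden-section fraction nearer the start of an interval: s = 2 - φ = (3 - √5)/2.
GOLDEN_S = (3.0 - math.sqrt(5.0)) / 2.0

#: |ν| below this (cm⁻¹) is numerical noise, not a real imaginary mode.
IMAG_FREQ_NOISE_CM = 30.0
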