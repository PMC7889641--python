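"""Physical constants in the internal unit system.

Units used throughout the package: length nm, energy kJ/mol, mass Da
(g/mol), time ps, charge in elementary charges, temperature K.  In this
system velocities come out in nm/ps and forces in kJ/mol/nm, the familiar
GROMACS-style convention.
"""
import math

from scipy import constants as _sc

#: Boltzmann constant, kJ mol^-1 K^-1 (equals the molar gas constant R/1000).
KB = _sc.R / 1000.0

#: Coulomb prefactor e^2 N_A / (4 pi eps0) in kJ nm mol^-1: energy of two
#: unit charges 1 nm apart in vacuum.
COULOMB_KJ_NM = (_sc.e**2 * _sc.N_A / (4.0 * math.pi * _sc.epsilon_0)) / 1000.0 * 1e9

#: 1 bar expressed in kJ mol^-1 nm^-3.
BAR = 1.0e5 * 1e-27 * _sc.N_A / 1000.0

#: 1 Da nm^-3 expressed in mg/mL.
DA_PER_NM3_IN_MG_PER_ML = 1e24 / _sc.N_A

#: Default Ashbaugh-Hatch well depth, kJ/mol (0.2 kcal/mol).
EPS_AH = 0.8368
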