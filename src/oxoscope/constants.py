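"""Single table of unit conversions used throughout the package.

All energies are stored in hartree in records, frequencies in cm^-1,
coordinates in angstrom, dipoles in debye; every cross-unit conversion in the
package goes through the constants below so that unit discipline is auditable
in one place. Values that are pure CODATA physics (Planck, Boltzmann, ...)
come from :mod:`scipy.constants`.
"""

from __future__ import annotations

import math

import scipy.constants as _sc

# --- energy ---------------------------------------------------------------
HARTREE_TO_KCAL = 627.5095          # 1 hartree in kcal/mol
CM1_TO_KCAL = 2.8591e-3             # 1 cm^-1 in kcal/mol (hc * N_A)
R_KCAL = 1.98720425864083e-3        # gas constant, kcal/(mol K)

# --- frequency / temperature ---------------------------------------------
HC_OVER_KB = 1.43877                # hc/k_B in cm K  (theta_vib = HC_OVER_KB * nu)
KB_OVER_H = 2.08366e10              # k_B/h in s^-1 K^-1 (Eyring prefactor / T)

# --- electrostatics -------------------------------------------------------
EANG_TO_DEBYE = 4.80321             # 1 e*angstrom in debye
VANG_TO_AU = 1.94469e-2             # 1 V/angstrom in atomic units of field
DEBYE_VANG_TO_KCAL = 4.8032         # 1 debye * (V/angstrom) in kcal/mol
COULOMB_E_ANG2_TO_VANG = 14.3996    # e/angstrom^2 -> V/angstrom (e/(4 pi eps0 A^2))

# --- derived factors for Hessian work (CODATA via scipy) ------------------
_AMU = _sc.atomic_mass
_BOHR = _sc.physical_constants["Bohr radius"][0]
_HARTREE_J = _sc.physical_constants["Hartree energy"][0]

#: sqrt(hartree / (amu bohr^2)) expressed as a wavenumber in cm^-1:
#: nu~ = sqrt(lambda) * HESS_EIG_TO_CM1 for mass-weighted Hessian eigenvalue
#: lambda in hartree/(amu bohr^2).
HESS_EIG_TO_CM1 = math.sqrt(_HARTREE_J / (_AMU * _BOHR**2)) / (2.0 * math.pi * _sc.c * 100.0)

# SI constants re-exported for the RRHO partition functions.
KB_SI = _sc.k
H_SI = _sc.h
AMU_SI = _AMU
ATM_PA = _sc.atm
N_A = _sc.N_A
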