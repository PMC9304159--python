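"""Rigid-rotor harmonic-oscillator (RRHO) thermochemistry and energy assembly.

Zero-point energies, thermal enthalpy and entropy corrections are evaluated
from harmonic wavenumbers (or from a Cartesian Hessian after mass weighting
and projection of overall translation/rotation). Composite electronic
energies are assembled as E_high + ZPE + E_solv (+ E_disp), or as full free
energies when thermal and entropic terms are requested.

Conventions: frequencies enter thermochemistry unscaled by default;
imaginary modes (negative wavenumbers) are excluded from all sums and
counted; symmetry number is fixed at 1; standard state is the ideal gas at
1 atm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import (
    AMU_SI,
    ATM_PA,
    CM1_TO_KCAL,
    HARTREE_TO_KCAL,
    HC_OVER_KB,
    HESS_EIG_TO_CM1,
    H_SI,
    KB_SI,
    R_KCAL,
)
from .masses import isotope_mass
from .qc_records import Geometry, QCRecord, SchemaError

#: moment-of-inertia eigenvalue below which a molecule is treated as linear
LINEAR_INERTIA_TOL = 1e-4  # amu angstrom^2

SCHEMES = ("E+ZPE+solv", "E+ZPE+solv+disp", "G")


@dataclass
class ThermoResult:
    """RRHO corrections at (T, P): ZPE/H_corr/G_corr in kcal/mol, S in cal/(mol K)."""

    zpe: float
    h_corr: float
    S: float
    g_corr: float
    T: float
    P: float
    n_imag: int
    warned_extra_imag: bool = False


@dataclass
class AssembledEnergy:
    """A composite energy (kcal/mol) with its additive component breakdown."""

    e_total: float
    components: dict[str, float]
    scheme: str


# ---------------------------------------------------------------------------
# Hessian -> frequencies
# ---------------------------------------------------------------------------


def _trans_rot_basis(masses: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n = len(masses)
    sqm = np.sqrt(masses)
    com = masses @ coords / masses.sum()
    r = coords - com
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sqm
        vecs.append(v.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        v = (sqm[:, None] * np.cross(e, r))
        vecs.append(v.ravel())
    D = np.array(vecs).T  # (3N, 6)
    # orthonormalize, dropping null rotations (atoms on the axis / linear case)
    u, s, _ = np.linalg.svd(D, full_matrices=False)
    rank = int(np.sum(s > 1e-8 * s[0]))
    return u[:, :rank]


def hessian_frequencies(
    hessian: np.ndarray, geometry: Geometry
) -> np.ndarray:
    """Harmonic wavenumbers (cm^-1, descending, imaginary negative).

    The Cartesian Hessian (hartree/bohr^2) is mass-weighted with the
    geometry's masses, overall translation and rotation are projected out,
    and the remaining 3N-6 (3N-5 for linear) eigenvalues are converted to
    wavenumbers, negative values flagging imaginary modes.
    """
    hessian = np.asarray(hessian, dtype=float)
    n = geometry.n_atoms
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError(
            f"hessian dimension {hessian.shape} does not match 3N={3 * n}")
    m3 = np.repeat(geometry.masses, 3)
    h_mw = hessian / np.sqrt(np.outer(m3, m3))
    basis = _trans_rot_basis(geometry.masses, geometry.coords)
    proj = np.eye(3 * n) - basis @ basis.T
    h_p = proj @ h_mw @ proj
    h_p = 0.5 * (h_p + h_p.T)
    eigvals = np.linalg.eigvalsh(h_p)
    nu = np.sign(eigvals) * np.sqrt(np.abs(eigvals)) * HESS_EIG_TO_CM1
    # drop the projected-out null modes: smallest |nu| entries
    n_tr = basis.shape[1]
    keep = np.argsort(np.abs(nu))[n_tr:]
    return np.sort(nu[keep])[::-1]


def isotope_frequencies(
    hessian: np.ndarray,
    geometry: Geometry,
    substitutions: dict[int, float | str] | None = None,
) -> np.ndarray:
    """Recompute harmonic wavenumbers after isotope substitution.

    ``substitutions`` maps 0-based atom indices to new masses in amu, or to
    isotope labels like ``'O18'`` / ``'D'``. An empty map reproduces the
    original spectrum.
    """
    subs: dict[int, float] = {}
    for idx, m in (substitutions or {}).items():
        subs[int(idx)] = isotope_mass(m) if isinstance(m, str) else float(m)
    return hessian_frequencies(hessian, geometry.with_masses(subs))


def scale_frequencies(frequencies: np.ndarray, scale: float) -> np.ndarray:
    """Scale real modes by *scale*; imaginary modes are reported unscaled."""
    if not 0 < scale <= 1.2:
        raise ValueError("frequency scale factor must be in (0, 1.2]")
    nu = np.asarray(frequencies, dtype=float)
    return np.where(nu > 0, nu * scale, nu)


# ---------------------------------------------------------------------------
# RRHO
# ---------------------------------------------------------------------------


def _vib_terms(real_nu: np.ndarray, T: float) -> tuple[float, float, float]:
    """(ZPE, thermal vibrational energy, vibrational entropy) in kcal/mol(/K)."""
    zpe = 0.5 * float(np.sum(real_nu)) * CM1_TO_KCAL
    theta = HC_OVER_KB * real_nu  # vibrational temperatures, K
    u = theta / T
    e_th = R_KCAL * float(np.sum(theta / np.expm1(u)))
    s_vib = R_KCAL * float(np.sum(u / np.expm1(u) - np.log(-np.expm1(-u))))
    return zpe, e_th, s_vib


def _trans_terms(total_mass_amu: float, T: float, P_atm: float) -> tuple[float, float]:
    """(thermal translational energy, translational entropy), kcal/mol(/K)."""
    m = total_mass_amu * AMU_SI
    q = (2.0 * math.pi * m * KB_SI * T / H_SI**2) ** 1.5 * (KB_SI * T / (P_atm * ATM_PA))
    s = R_KCAL * (math.log(q) + 2.5)
    return 1.5 * R_KCAL * T, s


def _rot_terms(geometry: Geometry, T: float) -> tuple[float, float]:
    """(thermal rotational energy, rotational entropy), sigma = 1."""
    if geometry.n_atoms == 1:
        return 0.0, 0.0
    com = geometry.center_of_mass()
    r = geometry.coords - com
    m = geometry.masses
    inertia = np.zeros((3, 3))
    for mi, ri in zip(m, r):
        inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    moments = np.sort(np.linalg.eigvalsh(inertia))  # amu angstrom^2
    moments_si = moments * AMU_SI * 1e-20
    b = 8.0 * math.pi**2 * KB_SI * T / H_SI**2
    if moments[0] < LINEAR_INERTIA_TOL:
        q = b * moments_si[2]
        return R_KCAL * T, R_KCAL * (math.log(q) + 1.0)
    q = math.sqrt(math.pi * b**3 * moments_si.prod())
    return 1.5 * R_KCAL * T, R_KCAL * (math.log(q) + 1.5)


def rrho(
    record: QCRecord,
    T: float = 298.15,
    P: float = 1.0,
    scale: float = 1.0,
) -> ThermoResult:
    """RRHO thermochemistry of *record* at temperature ``T`` (K), pressure ``P`` (atm).

    Frequencies come from the record directly or from its mass-weighted
    Hessian. Imaginary modes are excluded from every sum and counted in
    ``n_imag``; more than one imaginary mode raises a warning but the modes
    are still excluded. Translational/rotational contributions require a
    geometry; without one only the vibrational terms are evaluated.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    source = record.vibrational_input()
    if source == "frequencies":
        nu = np.asarray(record.frequencies, dtype=float)
    else:
        nu = hessian_frequencies(record.hessian, record.geometry)
    nu = scale_frequencies(nu, scale)
    real = nu[nu > 0]
    n_imag = int(np.sum(nu < 0))
    warned = False
    if n_imag > 1:
        warnings.warn(
            f"record {record.label!r}: {n_imag} imaginary modes excluded "
            "(expected at most one)", stacklevel=2)
        warned = True
    if real.size == 0 and record.geometry is None:
        raise SchemaError(
            f"record {record.label!r}: no real modes and no geometry; "
            "nothing to evaluate")

    zpe, e_vib, s_vib = _vib_terms(real, T) if real.size else (0.0, 0.0, 0.0)
    if record.geometry is not None:
        e_trans, s_trans = _trans_terms(float(record.geometry.masses.sum()), T, P)
        e_rot, s_rot = _rot_terms(record.geometry, T)
        h_corr = zpe + e_vib + e_trans + e_rot + R_KCAL * T  # + PV for H = U + RT
        s_kcal = s_vib + s_trans + s_rot
    else:
        h_corr = zpe + e_vib
        s_kcal = s_vib
    g_corr = h_corr - T * s_kcal
    return ThermoResult(
        zpe=zpe, h_corr=h_corr, S=s_kcal * 1000.0, g_corr=g_corr,
        T=T, P=P, n_imag=n_imag, warned_extra_imag=warned)


# ---------------------------------------------------------------------------
# composite energies
# ---------------------------------------------------------------------------


def assemble(record: QCRecord, thermo: ThermoResult, scheme: str) -> AssembledEnergy:
    """Assemble a composite energy for *record* under *scheme*.

    ``E+ZPE+solv``: E_high + ZPE + E_solv. ``E+ZPE+solv+disp`` adds the
    dispersion correction. ``G`` further adds the thermal enthalpy beyond ZPE
    and the -T*S term, i.e. E_high + E_solv + E_disp + G_corr.
    All components are reported in kcal/mol and sum exactly to ``e_total``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    components: dict[str, float] = {"E_high": record.e_high * HARTREE_TO_KCAL,
                                    "ZPE": thermo.zpe}
    if record.e_solv is None:
        raise SchemaError(
            f"record {record.label!r}: scheme {scheme!r} requires E_solv "
            "but the record does not provide it")
    components["E_solv"] = record.e_solv * HARTREE_TO_KCAL
    if scheme in ("E+ZPE+solv+disp", "G"):
        if record.e_disp is None:
            raise SchemaError(
                f"record {record.label!r}: scheme {scheme!r} requires E_disp "
                "but the record does not provide it")
        components["E_disp"] = record.e_disp * HARTREE_TO_KCAL
    if scheme == "G":
        components["thermal"] = thermo.h_corr - thermo.zpe
        components["-TS"] = -thermo.T * thermo.S / 1000.0
    return AssembledEnergy(
        e_total=float(sum(components.values())),
        components=components,
        scheme=scheme,
    )
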