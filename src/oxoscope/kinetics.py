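"""Transition-state-theory kinetics, kinetic isotope effects and branching.

Eyring rates with transmission coefficient 1, the Eyring KIE
``exp((dG_D - dG_H)/RT)``, the Wigner tunnelling factor
``Q_t = 1 + (h c nu / k_B T)^2 / 24`` built on the transition state's
imaginary-mode magnitude, and Curtin-Hammett (Boltzmann) branching ratios
over competing pathways sharing one reactant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .constants import HC_OVER_KB, KB_OVER_H, R_KCAL

DEFAULT_T = 298.15  # K


@dataclass
class RateResult:
    k: float            # s^-1
    dg_act: float       # kcal/mol
    T: float            # K
    kappa: float = 1.0


@dataclass
class KIEResult:
    dg_h: float
    dg_d: float
    nu_h: float
    nu_d: float
    kie_eyring: float
    qt_h: float
    qt_d: float
    kie_wigner: float
    T: float


@dataclass
class BranchingResult:
    pathways: list[str]
    dg_act: dict[str, float]
    fractions: dict[str, float]
    T: float
    scale: str = "G"  # which energy scale the barriers were quoted on


def dg_from_rate(k: float, T: float) -> float:
    """Activation free energy (kcal/mol) from a first-order rate constant.

    Inverts the Eyring equation k = (k_B T / h) exp(-dG/RT) with kappa = 1.
    """
    if k <= 0:
        raise ValueError("rate constant must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * T * math.log(KB_OVER_H * T / k)


def rate_from_dg(dg_act: float, T: float, kappa: float = 1.0) -> RateResult:
    """Eyring rate constant (s^-1) from an activation free energy (kcal/mol)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    k = kappa * KB_OVER_H * T * math.exp(-dg_act / (R_KCAL * T))
    return RateResult(k=k, dg_act=dg_act, T=T, kappa=kappa)


def kie_eyring(dg_h: float, dg_d: float, T: float = DEFAULT_T) -> float:
    """Eyring (semiclassical) KIE from H and D activation free energies."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp((dg_d - dg_h) / (R_KCAL * T))


def wigner_qt(nu: float, T: float = DEFAULT_T) -> float:
    """Wigner tunnelling factor from the imaginary-mode magnitude (cm^-1)."""
    if nu < 0:
        raise ValueError("pass the magnitude of the imaginary wavenumber")
    if T <= 0:
        raise ValueError("temperature must be positive")
    u = HC_OVER_KB * nu / T
    return 1.0 + u * u / 24.0


def kie_wigner(
    dg_h: float,
    dg_d: float,
    nu_h: float,
    nu_d: float,
    T: float = DEFAULT_T,
) -> KIEResult:
    """Wigner-corrected KIE: KIE_eyring * Q_t,H / Q_t,D.

    ``nu_h``/``nu_d`` are the magnitudes of the transition state's imaginary
    mode for the protio and deuterio systems (the deuterated frequencies are
    typically obtained from :func:`oxoscope.thermochem.isotope_frequencies`
    with both prochiral hydrogens replaced by deuterium).
    """
    if nu_d > nu_h:
        warnings.warn(
            "imaginary mode larger for D than H; unphysical for H transfer",
            stacklevel=2)
    eyr = kie_eyring(dg_h, dg_d, T)
    qt_h = wigner_qt(abs(nu_h), T)
    qt_d = wigner_qt(abs(nu_d), T)
    return KIEResult(
        dg_h=dg_h, dg_d=dg_d, nu_h=nu_h, nu_d=nu_d,
        kie_eyring=eyr, qt_h=qt_h, qt_d=qt_d,
        kie_wigner=eyr * qt_h / qt_d, T=T)


def branching(
    dg_act: dict[str, float],
    T: float = DEFAULT_T,
    scale: str = "G",
) -> BranchingResult:
    """Curtin-Hammett branching fractions over competing pathways.

    Assumes a common, rapidly equilibrating reactant and irreversible first
    steps, so fraction_i is proportional to exp(-dG_i / RT). Fractions are
    invariant to shifting all barriers by a constant.
    """
    if len(dg_act) < 2:
        raise ValueError("branching needs at least two pathways")
    if T <= 0:
        raise ValueError("temperature must be positive")
    ref = min(dg_act.values())
    weights = {p: math.exp(-(dg - ref) / (R_KCAL * T)) for p, dg in dg_act.items()}
    total = sum(weights.values())
    fractions = {p: w / total for p, w in weights.items()}
    return BranchingResult(
        pathways=list(dg_act), dg_act=dict(dg_act),
        fractions=fractions, T=T, scale=scale)
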