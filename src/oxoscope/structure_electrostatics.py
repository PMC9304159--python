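"""Protein-level point-charge electrostatics from PDB structures.

Charged-residue census (Asp/Glu negative; Arg/Lys positive; His positive
only when explicitly flagged protonated), formal-charge placement at
side-chain representative atoms, the resulting point-charge dipole vector,
and the Coulomb field at a site (vacuum by default). This is deliberately
coarse, direction-of-dipole electrostatics, not Poisson-Boltzmann.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_E_ANG2_TO_VANG, EANG_TO_DEBYE
from .qc_records import ProteinStructure

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-state variants
    "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX",
}
_HIS_NAMES = {"HIS", "HID", "HIE", "HIP"}

NEGATIVE = {"ASP", "GLU"}
POSITIVE = {"ARG", "LYS"}

#: side-chain atom bearing the formal charge, per residue type
REPRESENTATIVE_ATOM = {
    "ASP": "CG",
    "GLU": "CD",
    "ARG": "CZ",
    "LYS": "NZ",
    # protonated His: midpoint of the two ring nitrogens (handled specially)
}

MIN_CHARGE_DISTANCE = 0.5  # angstrom


@dataclass
class ResidueCensus:
    counts: dict[str, int]
    n_negative: int
    n_positive: int
    net_charge: int
    his_protonated: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class PointCharge:
    q: float
    xyz: np.ndarray
    res_name: str
    res_num: int
    chain: str


@dataclass
class ChargeModel:
    charges: list[PointCharge]

    def positions(self) -> np.ndarray:
        return np.array([c.xyz for c in self.charges], dtype=float)

    def values(self) -> np.ndarray:
        return np.array([c.q for c in self.charges], dtype=float)

    @property
    def net_charge(self) -> float:
        return float(sum(c.q for c in self.charges))


def _normalize_his_ids(his_protonated) -> set[tuple[str, int]]:
    ids = set()
    for item in his_protonated or []:
        if isinstance(item, str) and ":" in item:  # "A:70"
            chain, num = item.split(":", 1)
            ids.add((chain, int(num)))
        else:
            chain, num = item
            ids.add((str(chain), int(num)))
    return ids


def residue_census(
    structure: ProteinStructure,
    his_protonated=None,
) -> ResidueCensus:
    """Count residue types and formal charges over unique (chain, resnum).

    HETATM residues are excluded from the amino-acid tally. His residues
    count as positive only when listed in ``his_protonated`` (residue ids as
    ``(chain, resnum)`` or ``"chain:resnum"`` strings).
    """
    if not structure.records:
        raise ValueError("empty structure")
    his_ids = _normalize_his_ids(his_protonated)
    counts: dict[str, int] = {}
    n_neg = n_pos = 0
    flagged: list[tuple[str, int]] = []
    for (chain, resnum), resname, atoms in structure.residues():
        if atoms[0].het or resname not in AMINO_ACIDS:
            continue
        canonical = "HIS" if resname in _HIS_NAMES else resname
        counts[canonical] = counts.get(canonical, 0) + 1
        if canonical in NEGATIVE:
            n_neg += 1
        elif canonical in POSITIVE:
            n_pos += 1
        elif canonical == "HIS" and (chain, resnum) in his_ids:
            n_pos += 1
            flagged.append((chain, resnum))
    if not counts:
        raise ValueError("structure contains no amino-acid residues")
    return ResidueCensus(
        counts=counts, n_negative=n_neg, n_positive=n_pos,
        net_charge=n_pos - n_neg, his_protonated=flagged)


def charge_model(
    structure: ProteinStructure,
    his_protonated=None,
    overrides: dict[tuple[str, int], float] | None = None,
) -> ChargeModel:
    """Formal point charges at side-chain representative atoms.

    Asp/Glu -1 at CG/CD, Arg/Lys +1 at CZ/NZ, flagged His +1 at the ring
    nitrogens' midpoint; everything else 0 (omitted). ``overrides`` replaces
    the formal charge of specific ``(chain, resnum)`` residues before any
    moment computation. Falls back to the residue centroid when the
    representative atom is absent.
    """
    his_ids = _normalize_his_ids(his_protonated)
    overrides = overrides or {}
    charges: list[PointCharge] = []
    for (chain, resnum), resname, atoms in structure.residues():
        if atoms[0].het or resname not in AMINO_ACIDS:
            continue
        canonical = "HIS" if resname in _HIS_NAMES else resname
        if (chain, resnum) in overrides:
            q = overrides[(chain, resnum)]
        elif canonical in NEGATIVE:
            q = -1.0
        elif canonical in POSITIVE:
            q = +1.0
        elif canonical == "HIS" and (chain, resnum) in his_ids:
            q = +1.0
        else:
            continue
        if q == 0.0:
            continue
        pos = _charge_site(canonical, atoms)
        charges.append(PointCharge(q=q, xyz=pos, res_name=canonical,
                                   res_num=resnum, chain=chain))
    return ChargeModel(charges=charges)


def _charge_site(resname: str, atoms) -> np.ndarray:
    by_name = {a.atom_name: np.array(a.xyz) for a in atoms}
    if resname == "HIS":
        ring = [by_name[n] for n in ("ND1", "NE2") if n in by_name]
        if ring:
            return np.mean(ring, axis=0)
    else:
        rep = REPRESENTATIVE_ATOM.get(resname)
        if rep in by_name:
            return by_name[rep]
    return np.mean([np.array(a.xyz) for a in atoms], axis=0)


def dipole_from_charges(model: ChargeModel, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Point-charge dipole vector in debye: sum q_i (r_i - origin) * 4.80321.

    Translation-invariant only for net-neutral charge sets; for net-charged
    systems the origin (e.g. the reaction centre) must be stated with the
    result.
    """
    if not model.charges:
        return np.zeros(3)
    origin = np.asarray(origin, dtype=float)
    r = model.positions() - origin
    return (model.values() @ r) * EANG_TO_DEBYE


def field_at_point(
    model: ChargeModel,
    point,
    dielectric: float = 1.0,
) -> np.ndarray:
    """Coulomb field (V/A) at *point* from the model's point charges.

    Vacuum Coulomb sum ``sum q_i (r - r_i)/|r - r_i|^3 * 14.3996``; an
    optional uniform dielectric divides the result. Points within 0.5 A of
    any charge are rejected as singular.
    """
    point = np.asarray(point, dtype=float)
    if not model.charges:
        return np.zeros(3)
    d = point - model.positions()
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < MIN_CHARGE_DISTANCE):
        idx = int(np.argmin(dist))
        c = model.charges[idx]
        raise ValueError(
            f"point is {dist[idx]:.3f} A from charge on {c.res_name} "
            f"{c.chain}:{c.res_num} (< {MIN_CHARGE_DISTANCE} A)")
    contrib = (model.values() / dist**3)[:, None] * d
    return contrib.sum(axis=0) * COULOMB_E_ANG2_TO_VANG / dielectric
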