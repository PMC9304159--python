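"""Reaction-landscape bookkeeping for stepwise C-H hydroxylation.

Stationary points (reactant complex ``Re``, hydrogen-atom-abstraction
transition state ``TS1_HA``, radical intermediate ``IM1``, rebound
transition state ``TS2_reb``, product ``P``) are organized per model, spin
state and pathway (``C1R``/``C1S``/``C2R``/``C2S``), and reduced to
relative-energy tables, spin-state orderings, rate-determining steps,
selectivity verdicts with Boltzmann branching, group spin densities and
hydrogen-bond censuses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .qc_records import Geometry, ProteinStructure, QCRecord, SchemaError
from .thermochem import assemble, rrho

ROLES = ("Re", "TS1_HA", "IM1", "TS2_reb", "P")
TS_ROLES = ("TS1_HA", "TS2_reb")
PATHWAYS = ("C1R", "C1S", "C2R", "C2S", "none")

#: summed-fraction thresholds for the dominant-carbon call
DOMINANT_THRESHOLD = 0.9
PREFERRED_THRESHOLD = 0.5


@dataclass
class StationaryPoint:
    """A QCRecord tagged with its mechanistic role in a landscape.

    ``estimated`` marks barriers obtained from constraint scans rather than
    located transition states; such points are excluded from rate-determining
    -step analysis.
    """

    record: QCRecord
    role: str
    pathway: str = "none"
    spin: int | None = None
    model: str = ""
    config_label: str | None = None
    estimated: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.pathway not in PATHWAYS:
            raise ValueError(
                f"unknown pathway {self.pathway!r}; expected one of {PATHWAYS}")
        if self.spin is None:
            self.spin = self.record.multiplicity
        if self.record.frequencies is not None:
            n_imag = self.record.n_imag
            if self.role in TS_ROLES and n_imag != 1:
                raise ValueError(
                    f"{self.record.label!r}: TS role {self.role} requires exactly "
                    f"one imaginary mode, found {n_imag}")
            if self.role not in TS_ROLES and n_imag != 0:
                raise ValueError(
                    f"{self.record.label!r}: role {self.role} must have no "
                    f"imaginary modes, found {n_imag}")

    @property
    def slice_key(self) -> tuple[str, int]:
        return (self.model, self.spin)


@dataclass
class Landscape:
    """A validated set of stationary points sharing reference reactants."""

    points: list[StationaryPoint]
    scheme: str = "E+ZPE+solv+disp"
    T: float = 298.15
    P: float = 1.0

    def __post_init__(self) -> None:
        for key in {p.slice_key for p in self.points}:
            refs = [p for p in self.points
                    if p.slice_key == key and p.role == "Re"]
            if len(refs) != 1:
                raise ValueError(
                    f"slice (model={key[0]!r}, spin={key[1]}) needs exactly one "
                    f"Re reference, found {len(refs)}")
        # every pathway with a TS2 must have an IM1 to rebound from
        for p in self.points:
            if p.role == "TS2_reb" and not any(
                q.role == "IM1" and q.slice_key == p.slice_key
                and (q.pathway == p.pathway or q.pathway[:2] == p.pathway[:2])
                for q in self.points
            ):
                raise ValueError(
                    f"pathway {p.pathway} has a TS2 ({p.record.label!r}) but "
                    "no IM1 intermediate")

    def reference(self, model: str, spin: int) -> StationaryPoint:
        for p in self.points:
            if p.slice_key == (model, spin) and p.role == "Re":
                return p
        raise KeyError(f"no reference Re for (model={model!r}, spin={spin})")

    def _assembled(self, point: StationaryPoint, scheme: str) -> float:
        try:
            thermo = rrho(point.record, T=self.T, P=self.P)
            return assemble(point.record, thermo, scheme).e_total
        except SchemaError as exc:
            raise SchemaError(
                f"point {point.record.label!r} ({point.role}, {point.pathway}): "
                f"{exc}") from exc


def relative_table(landscape: Landscape) -> pd.DataFrame:
    """Relative energies (kcal/mol) of every point against its slice's Re.

    Returns a DataFrame with both the landscape's base scale (``dE_zpe``,
    by default E+ZPE+solv+disp) and the free-energy scale (``dG``); the
    reference row is exactly zero on both.
    """
    rows = []
    ref_cache: dict[tuple[str, int, str], float] = {}

    def ref_energy(key: tuple[str, int], scheme: str) -> float:
        ck = (*key, scheme)
        if ck not in ref_cache:
            ref = landscape.reference(*key)
            ref_cache[ck] = landscape._assembled(ref, scheme)
        return ref_cache[ck]

    for p in landscape.points:
        base = landscape._assembled(p, landscape.scheme)
        free = landscape._assembled(p, "G")
        rows.append({
            "label": p.record.label,
            "model": p.model,
            "spin": p.spin,
            "pathway": p.pathway,
            "role": p.role,
            "estimated": p.estimated,
            "dE_zpe": base - ref_energy(p.slice_key, landscape.scheme),
            "dG": free - ref_energy(p.slice_key, "G"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spin-state ordering
# ---------------------------------------------------------------------------


@dataclass
class SpinOrdering:
    ground_multiplicity: int
    ordering: list[tuple[int, float]]  # (multiplicity, gap above ground), ascending


def spin_ordering_from_energies(energies: dict[int, float]) -> SpinOrdering:
    """Order spin states by energy; gaps relative to the ground state."""
    if len(energies) != len(set(energies)):
        raise ValueError("duplicate multiplicity")
    ground = min(energies.values())
    ordered = sorted(energies.items(), key=lambda kv: (kv[1], kv[0]))
    return SpinOrdering(
        ground_multiplicity=ordered[0][0],
        ordering=[(m, e - ground) for m, e in ordered])


def spin_ordering(
    points: list[StationaryPoint],
    scheme: str = "E+ZPE+solv+disp",
    T: float = 298.15,
) -> SpinOrdering:
    """Spin-state ordering of one species (same model/role, >=2 multiplicities)."""
    if len(points) < 2:
        if len(points) == 1:
            return SpinOrdering(points[0].spin, [(points[0].spin, 0.0)])
        raise ValueError("spin ordering needs at least one point")
    seen: dict[int, float] = {}
    for p in points:
        if p.spin in seen:
            raise ValueError(f"duplicate multiplicity {p.spin}")
        thermo = rrho(p.record, T=T)
        seen[p.spin] = assemble(p.record, thermo, scheme).e_total
    return spin_ordering_from_energies(seen)


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------


@dataclass
class SelectivityVerdict:
    model: str
    barriers: dict[str, float]
    scale: str
    lowest_pathway: str
    window: float
    fractions: dict[str, float]
    carbon_fractions: dict[str, float]
    dominant_carbon: str          # 'C1', 'C2' or 'none'
    call: str                     # 'dominant', 'preferred' or 'unselective'
    T: float


def selectivity_from_barriers(
    barriers: dict[str, float],
    T: float = 298.15,
    model: str = "",
    scale: str = "G",
) -> SelectivityVerdict:
    """Selectivity verdict from per-pathway activation energies (kcal/mol)."""
    if len(barriers) < 2:
        raise ValueError("selectivity needs at least two pathways")
    branch = kinetics.branching(barriers, T=T, scale=scale)
    lowest = min(barriers, key=lambda p: barriers[p])
    window = max(barriers.values()) - min(barriers.values())
    carbons: dict[str, float] = {}
    for pathway, frac in branch.fractions.items():
        carbons[pathway[:2]] = carbons.get(pathway[:2], 0.0) + frac
    top = max(carbons, key=lambda c: carbons[c])
    ties = [c for c, f in carbons.items()
            if math.isclose(f, carbons[top], rel_tol=0.0, abs_tol=1e-9)]
    if len(ties) > 1:
        dominant, call = "none", "unselective"
    elif carbons[top] > DOMINANT_THRESHOLD:
        dominant, call = top, "dominant"
    elif carbons[top] >= PREFERRED_THRESHOLD:
        dominant, call = top, "preferred"
    else:
        dominant, call = "none", "unselective"
    return SelectivityVerdict(
        model=model, barriers=dict(barriers), scale=scale,
        lowest_pathway=lowest, window=window,
        fractions=branch.fractions, carbon_fractions=carbons,
        dominant_carbon=dominant, call=call, T=T)


def selectivity_report(
    landscape: Landscape, T: float | None = None
) -> dict[str, SelectivityVerdict]:
    """Per-model selectivity verdicts from the landscape's TS1 barriers.

    Uses free-energy barriers when thermal data is available (it always is
    for records carrying frequencies), recording the scale on the verdict.
    """
    T = landscape.T if T is None else T
    table = relative_table(landscape)
    ts1 = table[table["role"] == "TS1_HA"]
    out: dict[str, SelectivityVerdict] = {}
    for model, sub in ts1.groupby("model"):
        barriers = {row.pathway: row.dG for row in sub.itertuples()}
        if len(barriers) < 2:
            continue
        out[model] = selectivity_from_barriers(barriers, T=T, model=model, scale="G")
    if not out:
        raise ValueError("landscape has no model with >=2 TS1 pathways")
    return out


# ---------------------------------------------------------------------------
# rate-determining step
# ---------------------------------------------------------------------------


@dataclass
class RdsResult:
    label: str
    role: str
    energy: float
    tie: bool


def rds(landscape: Landscape, pathway: str) -> RdsResult:
    """Highest located TS of *pathway* relative to the reference.

    Scan-estimated barriers are excluded; ties are resolved toward the
    earlier mechanistic step and flagged.
    """
    table = relative_table(landscape)
    ts = table[
        (table["pathway"] == pathway)
        & table["role"].isin(TS_ROLES)
        & ~table["estimated"]
    ]
    if ts.empty:
        raise ValueError(f"pathway {pathway!r} has no located transition state")
    col = "dE_zpe"
    best = ts.loc[ts[col].idxmax()]
    tied = ts[np.isclose(ts[col], best[col], atol=1e-9)]
    tie = len(tied) > 1
    if tie:  # earlier mechanistic role wins
        tied = tied.copy()
        tied["order"] = tied["role"].map({r: i for i, r in enumerate(ROLES)})
        best = tied.loc[tied["order"].idxmin()]
    return RdsResult(label=best["label"], role=best["role"],
                     energy=float(best[col]), tie=tie)


# ---------------------------------------------------------------------------
# spin densities and hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class GroupSpin:
    groups: dict[str, float]
    remainder: float
    total: float


def group_spin(record: QCRecord, groups: dict[str, list[int]]) -> GroupSpin:
    """Sum per-atom spin densities over named, disjoint atom-index groups."""
    if record.spin_densities is None:
        raise SchemaError(f"record {record.label!r} has no spin densities")
    rho = record.spin_densities
    seen: set[int] = set()
    sums: dict[str, float] = {}
    for name, idxs in groups.items():
        for i in idxs:
            if not 0 <= i < len(rho):
                raise IndexError(f"group {name!r}: atom index {i} out of range")
            if i in seen:
                raise ValueError(f"group {name!r}: atom index {i} reused; "
                                 "groups must be disjoint")
            seen.add(i)
        sums[name] = float(sum(rho[i] for i in idxs))
    remainder = float(sum(rho[i] for i in range(len(rho)) if i not in seen))
    return GroupSpin(groups=sums, remainder=remainder, total=float(rho.sum()))


@dataclass
class Contact:
    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float
    angle: float | None


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, Geometry):
        return obj.coords
    if isinstance(obj, ProteinStructure):
        return np.array([r.xyz for r in obj.records], dtype=float)
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def hbond_census(
    obj,
    donors,
    acceptors,
    d_max: float = 2.5,
    angle_min: float = 120.0,
    mode: str = "auto",
) -> list[Contact]:
    """Hydrogen-bond contacts among the given donor/acceptor atoms.

    ``donors`` may be ``(donor_index, hydrogen_index)`` pairs, in which case
    the D-H...A angle criterion applies and distances are H...A; or bare
    indices for distance-only mode (no hydrogens resolved), where the
    distance is D...A and no angle is checked. ``obj`` is a Geometry, a
    ProteinStructure or a raw (N, 3) coordinate array. ``mode`` may force
    ``'angle'`` or ``'distance'``; the default infers it from the donors.
    """
    coords = _coords_of(obj)
    contacts: list[Contact] = []
    pair_mode = len(donors) > 0 and isinstance(donors[0], (tuple, list))
    if mode == "angle" and not pair_mode:
        raise ValueError(
            "angle criterion requested but donors carry no hydrogen indices; "
            "use distance-only mode (bare donor indices)")
    if mode == "distance":
        donors = [d[0] if isinstance(d, (tuple, list)) else d for d in donors]
        pair_mode = False
    for d in donors:
        if pair_mode:
            d_idx, h_idx = d
            for a in acceptors:
                if a in (d_idx, h_idx):
                    continue
                vec_ha = coords[a] - coords[h_idx]
                dist = float(np.linalg.norm(vec_ha))
                if dist > d_max:
                    continue
                vec_hd = coords[d_idx] - coords[h_idx]
                cosang = np.dot(vec_hd, vec_ha) / (
                    np.linalg.norm(vec_hd) * dist)
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_min:
                    contacts.append(Contact(d_idx, h_idx, a, dist, angle))
        else:
            for a in acceptors:
                if a == d:
                    continue
                dist = float(np.linalg.norm(coords[a] - coords[d]))
                if dist <= d_max:
                    contacts.append(Contact(d, None, a, dist, None))
    return contacts
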