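"""Record data model and file I/O.

Defines the three containers the rest of the package computes on —
:class:`Geometry`, :class:`QCRecord` and :class:`ProteinStructure` — plus
readers/writers for the structured QC-record text format (YAML with an
explicit unit header, one species per file), standard XYZ geometries, and
PDB protein structures (parsed with :mod:`gemmi`).

Unit discipline: energies hartree, frequencies cm^-1, coordinates angstrom,
dipoles debye, Hessians hartree/bohr^2, masses amu. Conversions happen only
downstream through :mod:`oxoscope.constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import yaml

from .masses import MOST_ABUNDANT, mass_of

RECORD_FORMAT = "oxoscope-qc/1"
RECORD_UNITS = {
    "energy": "hartree",
    "frequency": "cm^-1",
    "length": "angstrom",
    "dipole": "debye",
    "hessian": "hartree/bohr^2",
    "mass": "amu",
}

# minimal Z table for the electron-parity check
ATOMIC_NUMBER = {
    "H": 1, "He": 2, "Li": 3, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9,
    "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17,
    "K": 19, "Ca": 20, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29,
    "Zn": 30, "Se": 34, "Br": 35, "I": 53,
}


class SchemaError(ValueError):
    """A record violates the documented schema (missing/invalid field)."""


class RecordParseError(ValueError):
    """A file could not be parsed as the record/PDB format."""


class EmptyStructureError(ValueError):
    """A PDB file contained no ATOM/HETATM records."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class Geometry:
    """Atomic positions with per-atom masses.

    ``elements`` are periodic-table symbols, ``masses`` amu (default: most
    abundant isotope), ``coords`` an (N, 3) array in angstrom.
    """

    elements: list[str]
    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) == 0:
            raise ValueError("geometry needs at least one atom")
        if not (len(self.elements) == len(self.masses) == len(self.coords)):
            raise ValueError("elements, masses and coords lengths differ")
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be positive")
        for el in self.elements:
            if el not in MOST_ABUNDANT:
                raise ValueError(f"unknown element symbol {el!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_atoms(cls, atoms: Sequence[tuple]) -> "Geometry":
        """Build from ``(element, mass, (x, y, z))`` or ``(element, (x, y, z))`` tuples."""
        elements, masses, coords = [], [], []
        for atom in atoms:
            if len(atom) == 3:
                el, m, xyz = atom
            else:
                el, xyz = atom
                m = mass_of(el)
            elements.append(el)
            masses.append(float(m))
            coords.append(tuple(float(c) for c in xyz))
        return cls(elements, np.array(masses), np.array(coords))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_masses(self, substitutions: dict[int, float]) -> "Geometry":
        """Copy with masses replaced at the given 0-based atom indices."""
        masses = self.masses.copy()
        for idx, m in substitutions.items():
            if not 0 <= idx < self.n_atoms:
                raise IndexError(f"atom index {idx} out of range (N={self.n_atoms})")
            if m <= 0:
                raise ValueError("substituted mass must be positive")
            masses[idx] = m
        return Geometry(list(self.elements), masses, self.coords.copy())

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()

    def to_xyz(self, comment: str = "") -> str:
        lines = [str(self.n_atoms), comment]
        for el, (x, y, z) in zip(self.elements, self.coords):
            lines.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
        return "\n".join(lines) + "\n"


def geometry_from_xyz(text: str) -> Geometry:
    """Parse a standard XYZ block (angstrom); masses default per element."""
    lines = text.strip().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise RecordParseError("XYZ: first line must be the atom count") from exc
    atoms = []
    for i, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise RecordParseError(f"XYZ: malformed atom line {i}")
        atoms.append((parts[0], (float(parts[1]), float(parts[2]), float(parts[3]))))
    if len(atoms) != n:
        raise RecordParseError("XYZ: atom count does not match header")
    return Geometry.from_atoms(atoms)


# ---------------------------------------------------------------------------
# QCRecord
# ---------------------------------------------------------------------------


@dataclass
class QCRecord:
    """One species' quantum-chemistry results.

    Energies in hartree (``e_high`` the single-point level, ``e_low`` the
    optimization level, ``e_solv``/``e_disp`` corrections), harmonic
    frequencies in cm^-1 with imaginary modes encoded as *negative*
    wavenumbers, Cartesian Hessian in hartree/bohr^2, dipole in debye,
    per-atom spin densities in unpaired electrons.
    """

    label: str
    charge: int
    multiplicity: int
    e_high: float
    e_low: float | None = None
    e_solv: float | None = None
    e_disp: float | None = None
    frequencies: np.ndarray | None = None
    hessian: np.ndarray | None = None
    dipole: np.ndarray | None = None
    spin_densities: np.ndarray | None = None
    geometry: Geometry | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.multiplicity) < 1:
            raise SchemaError("multiplicity must be an integer >= 1")
        self.charge = int(self.charge)
        self.multiplicity = int(self.multiplicity)
        for attr in ("frequencies", "dipole", "spin_densities"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))
        if self.dipole is not None and self.dipole.shape != (3,):
            raise SchemaError("dipole must be a 3-vector")
        if self.hessian is not None:
            self.hessian = np.asarray(self.hessian, dtype=float)
            n = self.hessian.shape[0]
            if self.hessian.shape != (n, n):
                raise SchemaError("hessian must be square")
            if self.geometry is not None and n != 3 * self.geometry.n_atoms:
                raise SchemaError(
                    f"hessian dimension {n} != 3N={3 * self.geometry.n_atoms}")
            if not np.allclose(self.hessian, self.hessian.T, atol=1e-8):
                raise SchemaError("hessian is not symmetric within tolerance")
        self._check_spin_parity()

    def _check_spin_parity(self) -> None:
        # only checkable when charge and geometry (hence electron count) are known
        if self.geometry is None:
            return
        try:
            n_elec = sum(ATOMIC_NUMBER[el] for el in self.geometry.elements) - self.charge
        except KeyError:
            return
        # even electron count -> odd multiplicity and vice versa
        if (n_elec + self.multiplicity) % 2 == 0:
            raise SchemaError(
                f"multiplicity {self.multiplicity} inconsistent with "
                f"{n_elec} electrons")

    @property
    def e_solv_or0(self) -> float:
        return 0.0 if self.e_solv is None else self.e_solv

    @property
    def e_disp_or0(self) -> float:
        return 0.0 if self.e_disp is None else self.e_disp

    # -- thermochemistry preconditions -----------------------------------
    def vibrational_input(self) -> str:
        """Which vibrational data is present: 'frequencies', 'hessian' or raise."""
        if self.frequencies is not None:
            return "frequencies"
        if self.hessian is not None:
            if self.geometry is None:
                raise SchemaError(
                    f"record {self.label!r}: hessian without geometry cannot be "
                    "mass-weighted")
            return "hessian"
        raise SchemaError(
            f"record {self.label!r} has neither frequencies nor hessian; "
            "thermochemistry needs exactly one of them")

    @property
    def n_imag(self) -> int:
        if self.frequencies is None:
            return 0
        return int(np.sum(self.frequencies < 0))


# ---------------------------------------------------------------------------
# record file I/O
# ---------------------------------------------------------------------------

_MANDATORY = ("label", "charge", "multiplicity", "e_high")
_KNOWN_KEYS = {
    "format", "units", "label", "charge", "multiplicity", "e_high", "e_low",
    "e_solv", "e_disp", "frequencies", "hessian", "dipole", "spin_densities",
    "geometry",
}


def _as_float(value, key: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise RecordParseError(f"key {key!r}: expected a number, got {value!r}")
    return float(value)


def read_qc_record(path: str | Path) -> QCRecord:
    """Read a QC-record file; unknown keys are preserved in ``record.extra``."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise RecordParseError(f"{path}: not valid record syntax: {exc}") from exc
    if not isinstance(data, dict):
        raise RecordParseError(f"{path}: record file must be a mapping")
    if data.get("format") != RECORD_FORMAT:
        raise SchemaError(f"{path}: missing or unsupported 'format' "
                          f"(expected {RECORD_FORMAT!r})")
    for key in _MANDATORY:
        if key not in data:
            raise SchemaError(f"{path}: missing mandatory field {key!r}")
    for key in ("e_high", "e_low", "e_solv", "e_disp"):
        if data.get(key) is not None:
            data[key] = _as_float(data[key], key)

    geometry = None
    if data.get("geometry") is not None:
        atoms = data["geometry"].get("atoms")
        if not atoms:
            raise SchemaError(f"{path}: geometry block without atoms")
        geometry = Geometry.from_atoms(
            [(a[0], a[1], tuple(a[2:5])) for a in atoms])

    extra = {k: v for k, v in data.items() if k not in _KNOWN_KEYS}
    return QCRecord(
        label=str(data["label"]),
        charge=int(data["charge"]),
        multiplicity=int(data["multiplicity"]),
        e_high=float(data["e_high"]),
        e_low=data.get("e_low"),
        e_solv=data.get("e_solv"),
        e_disp=data.get("e_disp"),
        frequencies=data.get("frequencies"),
        hessian=data.get("hessian"),
        dipole=data.get("dipole"),
        spin_densities=data.get("spin_densities"),
        geometry=geometry,
        extra=extra,
    )


def write_qc_record(record: QCRecord, path: str | Path) -> None:
    """Write *record* so that :func:`read_qc_record` reproduces it exactly."""
    data: dict = {
        "format": RECORD_FORMAT,
        "units": dict(RECORD_UNITS),
        "label": record.label,
        "charge": record.charge,
        "multiplicity": record.multiplicity,
        "e_high": float(record.e_high),
    }
    if record.e_low is not None:
        data["e_low"] = float(record.e_low)
    if record.e_solv is not None:
        data["e_solv"] = float(record.e_solv)
    if record.e_disp is not None:
        data["e_disp"] = float(record.e_disp)
    if record.frequencies is not None:
        data["frequencies"] = [float(v) for v in record.frequencies]
    if record.hessian is not None:
        data["hessian"] = [[float(v) for v in row] for row in record.hessian]
    if record.dipole is not None:
        data["dipole"] = [float(v) for v in record.dipole]
    if record.spin_densities is not None:
        data["spin_densities"] = [float(v) for v in record.spin_densities]
    if record.geometry is not None:
        g = record.geometry
        data["geometry"] = {
            "atoms": [
                [el, float(m), float(x), float(y), float(z)]
                for el, m, (x, y, z) in zip(g.elements, g.masses, g.coords)
            ]
        }
    data.update(record.extra)
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=False, default_flow_style=None))


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------


class AtomRecord(NamedTuple):
    res_name: str
    res_num: int
    chain: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    altloc: str
    model: int
    het: bool


@dataclass
class ProteinStructure:
    """Flat list of ATOM/HETATM records (first model, preferred altloc)."""

    records: list[AtomRecord]

    def residues(self) -> Iterator[tuple[tuple[str, int], str, list[AtomRecord]]]:
        """Iterate ``((chain, resnum), resname, atoms)`` in file order."""
        seen: dict[tuple[str, int], tuple[str, list[AtomRecord]]] = {}
        order: list[tuple[str, int]] = []
        for rec in self.records:
            key = (rec.chain, rec.res_num)
            if key not in seen:
                seen[key] = (rec.res_name, [])
                order.append(key)
            seen[key][1].append(rec)
        for key in order:
            resname, atoms = seen[key]
            yield key, resname, atoms

    @property
    def n_residues(self) -> int:
        return len({(r.chain, r.res_num) for r in self.records})


def _prescan_pdb(path: Path) -> None:
    """Cheap fixed-width sanity check so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise RecordParseError(
                        f"{path}:{lineno}: ATOM/HETATM line shorter than the "
                        "coordinate columns")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError as exc:
                    raise RecordParseError(
                        f"{path}:{lineno}: unparsable coordinate field") from exc


def read_pdb(path: str | Path, model: int = 1) -> ProteinStructure:
    """Read ATOM/HETATM records of one model (default: first) of a PDB file.

    When duplicate altloc conformers exist, blank or 'A' altlocs are kept.
    """
    import gemmi

    path = Path(path)
    _prescan_pdb(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise RecordParseError(f"{path}: PDB parse failed: {exc}") from exc

    if len(structure) == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    idx = min(model, len(structure)) - 1
    mdl = structure[idx]

    records: list[AtomRecord] = []
    for chain in mdl:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                records.append(AtomRecord(
                    res_name=residue.name,
                    res_num=residue.seqid.num,
                    chain=chain.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    altloc="" if atom.altloc in ("", "\0") else atom.altloc,
                    model=idx + 1,
                    het=residue.het_flag == "H",
                ))
    if not records:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    return ProteinStructure(records)
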