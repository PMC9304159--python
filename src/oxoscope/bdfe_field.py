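"""Bond dissociation free energies and their response to electric fields.

A homolytic C-H BDFE is ``G(R.) + G(H.) - G(RH)``. Under a uniform external
field F along a molecular axis u the first-order (Stark) response is
``BDFE(F) = BDFE(0) - (dmu . u) F`` with ``dmu`` the dipole change of
homolysis (radical + H atom minus parent), converted from debye * (V/A) to
kcal/mol. Crossing fields and per-field weakest-bond maps classify which
C-H bond an environment field weakens most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEBYE_VANG_TO_KCAL

AXES = {"x": np.array([1.0, 0.0, 0.0]),
        "y": np.array([0.0, 1.0, 0.0]),
        "z": np.array([0.0, 0.0, 1.0])}

MAX_FIELD = 1.0  # V/angstrom sanity bound


@dataclass
class BDFEResult:
    bond: str
    bdfe: float                   # kcal/mol
    g_radical: float
    g_h_atom: float
    g_parent: float
    medium: str = "gas"


@dataclass
class FieldScan:
    """Per-bond BDFE values over a signed field grid along one axis.

    The axis passes through the molecular centre of mass; ``+u`` means the
    field vector points along the positive axis direction (configurable by
    negating the grid).
    """

    axis: str
    fields: np.ndarray            # V/angstrom, signed
    bdfe: dict[str, np.ndarray]   # bond -> kcal/mol at each field
    model: str = "linear"

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        self.bdfe = {b: np.asarray(v, dtype=float) for b, v in self.bdfe.items()}
        for bond, vals in self.bdfe.items():
            if vals.shape != self.fields.shape:
                raise ValueError(f"bond {bond!r}: value grid does not match fields")


def bdfe(
    g_parent: float,
    g_radical: float,
    g_h_atom: float,
    bond: str = "",
    medium: str = "gas",
    schemes: tuple[str, str, str] | None = None,
) -> BDFEResult:
    """Homolytic BDFE from species free energies on one common scale.

    ``schemes`` optionally carries the assembly-scheme label of each input
    (parent, radical, H atom); mixing different schemes is an error.
    """
    if schemes is not None and len(set(schemes)) != 1:
        raise ValueError(f"mixed energy schemes {schemes}; BDFE components "
                         "must share one scheme")
    return BDFEResult(
        bond=bond,
        bdfe=g_radical + g_h_atom - g_parent,
        g_radical=g_radical, g_h_atom=g_h_atom, g_parent=g_parent,
        medium=medium)


def _axis_vector(axis) -> np.ndarray:
    if isinstance(axis, str):
        try:
            return AXES[axis]
        except KeyError:
            raise ValueError(f"unknown axis {axis!r}") from None
    u = np.asarray(axis, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("axis vector must be nonzero")
    return u / n


def stark_bdfe(
    bdfe0: float,
    dmu: np.ndarray,
    field: float,
    axis="y",
    model: str = "linear",
    dalpha: float | None = None,
) -> float:
    """BDFE (kcal/mol) under a uniform field (V/A) along *axis*.

    ``dmu`` is the homolysis dipole change in debye. The linear model is
    ``BDFE(0) - (dmu . u) F``; the quadratic model adds ``-0.5 dalpha F^2``
    when a polarizability difference (kcal/mol per (V/A)^2) is supplied.
    """
    if abs(field) > MAX_FIELD:
        raise ValueError(f"|F| = {abs(field)} exceeds the {MAX_FIELD} V/A bound")
    u = _axis_vector(axis)
    dmu = np.asarray(dmu, dtype=float)
    shift = -float(dmu @ u) * field * DEBYE_VANG_TO_KCAL
    if model == "quadratic":
        if dalpha is None:
            raise ValueError("quadratic model requires dalpha")
        shift += -0.5 * dalpha * field * field
    elif model != "linear":
        raise ValueError(f"unknown response model {model!r}")
    return bdfe0 + shift


def field_scan(
    bonds: dict[str, tuple[float, np.ndarray]],
    fields: np.ndarray,
    axis="y",
    model: str = "linear",
) -> FieldScan:
    """Build a :class:`FieldScan` from per-bond ``(BDFE(0), dmu)`` data."""
    fields = np.asarray(fields, dtype=float)
    axis_name = axis if isinstance(axis, str) else "custom"
    values = {
        bond: np.array([stark_bdfe(b0, dmu, f, axis=axis, model=model)
                        for f in fields])
        for bond, (b0, dmu) in bonds.items()
    }
    return FieldScan(axis=axis_name, fields=fields, bdfe=values, model=model)


def crossing_field(
    bond_a: tuple[float, float], bond_b: tuple[float, float]
) -> float | None | str:
    """Field (V/A) where two linear BDFE responses cross.

    Each bond is ``(BDFE(0), slope)`` with ``BDFE(F) = BDFE(0) + slope * F``.
    Returns the crossing field, ``None`` for parallel distinct lines, or
    ``'degenerate'`` for identical lines.
    """
    b0a, sa = bond_a
    b0b, sb = bond_b
    if sa == sb:
        return "degenerate" if b0a == b0b else None
    return (b0b - b0a) / (sa - sb)


def weakest_bond_map(scan: FieldScan) -> tuple[list[str], list[float]]:
    """Per-field weakest (lowest-BDFE) bond and the transition fields.

    Transition fields are linear-interpolated crossings between consecutive
    grid points where the argmin bond changes.
    """
    if len(scan.bdfe) < 2:
        if len(scan.bdfe) == 1:
            bond = next(iter(scan.bdfe))
            return [bond] * len(scan.fields), []
        raise ValueError("scan has no bonds")
    bonds = list(scan.bdfe)
    matrix = np.vstack([scan.bdfe[b] for b in bonds])  # (n_bonds, n_fields)
    argmin = matrix.argmin(axis=0)
    labels = [bonds[i] for i in argmin]
    transitions: list[float] = []
    for j in range(1, len(labels)):
        if labels[j] != labels[j - 1]:
            i0, i1 = argmin[j - 1], argmin[j]
            f0, f1 = scan.fields[j - 1], scan.fields[j]
            d0 = matrix[i0, j - 1] - matrix[i1, j - 1]
            d1 = matrix[i0, j] - matrix[i1, j]
            if d1 != d0:
                transitions.append(float(f0 - d0 * (f1 - f0) / (d1 - d0)))
            else:
                transitions.append(float(0.5 * (f0 + f1)))
    return labels, transitions


def dipole_alignment(mu: np.ndarray, bond_axis: np.ndarray) -> tuple[float, str]:
    """Cosine of the angle between a dipole and a bond axis, with a verdict.

    Classification at +-0.5: ``aligned`` (cos >= 0.5), ``anti-aligned``
    (cos <= -0.5), else ``orthogonal``.
    """
    mu = np.asarray(mu, dtype=float)
    axis = np.asarray(bond_axis, dtype=float)
    n_mu, n_ax = np.linalg.norm(mu), np.linalg.norm(axis)
    if n_mu == 0 or n_ax == 0:
        raise ValueError("dipole and bond axis must be nonzero vectors")
    cos = float(mu @ axis / (n_mu * n_ax))
    if cos >= 0.5:
        verdict = "aligned"
    elif cos <= -0.5:
        verdict = "anti-aligned"
    else:
        verdict = "orthogonal"
    return cos, verdict
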