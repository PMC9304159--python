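"""Isotope-pure atomic masses (most abundant isotope per element).

Isotope substitution (D for H, 18O for 16O) is a first-class operation in this
package, so the default mass of an element is that of its most abundant
isotope rather than the standard atomic weight. Individual atoms can always
carry an explicit mass override in a :class:`~oxoscope.qc_records.Geometry`.
"""

from __future__ import annotations

# mass of the most abundant isotope, in amu (CODATA/AME)
MOST_ABUNDANT: dict[str, float] = {
    "H": 1.00782503207,
    "He": 4.00260325415,
    "Li": 7.01600455,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Al": 26.98153863,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Mn": 54.9380451,
    "Fe": 55.9349375,
    "Co": 58.9331950,
    "Ni": 57.9353429,
    "Cu": 62.9295975,
    "Zn": 63.9291422,
    "Se": 79.9165213,
    "Br": 78.9183371,
    "I": 126.904473,
}

# named isotopes used in substitution work
ISOTOPES: dict[str, float] = {
    "D": 2.01410177785,
    "T": 3.01604927767,
    "H1": 1.00782503207,
    "H2": 2.01410177785,
    "O16": 15.99491461956,
    "O17": 16.99913170,
    "O18": 17.99916196,
    "C13": 13.0033548378,
    "N15": 15.0001088982,
    "Fe54": 53.9396105,
    "Fe56": 55.9349375,
    "Fe57": 56.9353940,
}


def mass_of(element: str) -> float:
    """Default (most-abundant-isotope) mass of *element* in amu."""
    try:
        return MOST_ABUNDANT[element]
    except KeyError:
        raise KeyError(f"no default mass tabulated for element {element!r}") from None


def isotope_mass(label: str) -> float:
    """Mass of a named isotope like ``'O18'`` or ``'D'`` in amu."""
    try:
        return ISOTOPES[label]
    except KeyError:
        raise KeyError(f"unknown isotope label {label!r}") from None


def nearest_element(mass: float) -> str:
    """Element whose default mass is closest to *mass* (fixture labelling aid)."""
    return min(MOST_ABUNDANT, key=lambda el: abs(MOST_ABUNDANT[el] - mass))
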