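"""Element reference data.

Standard atomic weights (IUPAC 2021 abridged values, unified atomic mass
units) for the elements a reaction-network exploration is likely to touch,
plus the default valences used when a total molecular charge has to be
attributed to a single atom.
"""

from __future__ import annotations

# IUPAC 2021 abridged standard atomic weights (u).  Conventional values are
# used for elements with an interval weight.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.098, "Ca": 40.078, "Sc": 44.956, "Ti": 47.867, "V": 50.942,
    "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693,
    "Cu": 63.546, "Zn": 65.38, "Ga": 69.723, "Ge": 72.630, "As": 74.922,
    "Se": 78.971, "Br": 79.904, "Kr": 83.798,
    "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224, "Nb": 92.906,
    "Mo": 95.95, "Tc": 97.0, "Ru": 101.07, "Rh": 102.91, "Pd": 106.42,
    "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71, "Sb": 121.76,
    "Te": 127.60, "I": 126.90, "Xe": 131.29,
    "Cs": 132.91, "Ba": 137.33, "La": 138.91, "Ce": 140.12,
    "Pt": 195.08, "Au": 196.97, "Hg": 200.59, "Tl": 204.38, "Pb": 207.2,
    "Bi": 208.98,
}

# Typical covalent valences; used only as a heuristic to place a nonzero
# total charge on the most valence-deficient atom when no per-atom formal
# charges are supplied.
DEFAULT_VALENCES: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}


def atomic_mass(element: str) -> float:
    """Standard atomic weight of *element* in u.

    Raises ``KeyError`` with a readable message for unknown symbols.
    """
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(f"unknown element symbol: {element!r}") from None


def is_element(symbol: str) -> bool:
    return symbol in ATOMIC_MASSES
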