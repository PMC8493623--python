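"""Element reference data: masses, covalent radii, van der Waals radii.

Masses are IUPAC 2021 standard atomic weights (abridged), covalent radii
the Cordero et al. single-bond values, van der Waals radii the Bondi set
with common extensions. All radii in Angstrom, masses in unified atomic
mass units.
"""

from __future__ import annotations

from .errors import PixkitError

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Ti": 22, "V": 23,
    "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30,
    "Ga": 31, "Ge": 32, "As": 33, "Se": 34, "Br": 35, "Kr": 36, "Rb": 37,
    "Sr": 38, "Zr": 40, "Mo": 42, "Ru": 44, "Rh": 45, "Pd": 46, "Ag": 47,
    "Cd": 48, "In": 49, "Sn": 50, "Sb": 51, "Te": 52, "I": 53, "Xe": 54,
    "Cs": 55, "Ba": 56, "W": 74, "Re": 75, "Os": 76, "Ir": 77, "Pt": 78,
    "Au": 79, "Hg": 80, "Tl": 81, "Pb": 82, "Bi": 83,
}

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845,
    "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Ga": 69.723,
    "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904, "Kr": 83.798,
    "Rb": 85.468, "Sr": 87.62, "Zr": 91.224, "Mo": 95.95, "Ru": 101.07,
    "Rh": 102.91, "Pd": 106.42, "Ag": 107.87, "Cd": 112.41, "In": 114.82,
    "Sn": 118.71, "Sb": 121.76, "Te": 127.60, "I": 126.90, "Xe": 131.29,
    "Cs": 132.91, "Ba": 137.33, "W": 183.84, "Re": 186.21, "Os": 190.23,
    "Ir": 192.22, "Pt": 195.08, "Au": 196.97, "Hg": 200.59, "Tl": 204.38,
    "Pb": 207.2, "Bi": 208.98,
}

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Ti": 1.60, "V": 1.53, "Cr": 1.39, "Mn": 1.39,
    "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22, "Ga": 1.22,
    "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16, "Rb": 2.20,
    "Sr": 1.95, "Zr": 1.75, "Mo": 1.54, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39,
    "Ag": 1.45, "Cd": 1.44, "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38,
    "I": 1.39, "Xe": 1.40, "Cs": 2.44, "Ba": 2.15, "W": 1.62, "Re": 1.51,
    "Os": 1.44, "Ir": 1.41, "Pt": 1.36, "Au": 1.36, "Hg": 1.32, "Tl": 1.45,
    "Pb": 1.46, "Bi": 1.48,
}

# Bondi radii; elements Bondi did not list fall back to 2.0 A downstream.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20, "He": 1.40, "Li": 1.81, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Ar": 1.88, "K": 2.75, "Ga": 1.87, "As": 1.85,
    "Se": 1.90, "Br": 1.85, "Kr": 2.02, "In": 1.93, "Sn": 2.17, "Sb": 2.06,
    "Te": 2.06, "I": 1.98, "Xe": 2.16, "Tl": 1.96, "Pb": 2.02, "B": 1.92,
}

DEFAULT_VDW_RADIUS = 2.0


def normalize_symbol(raw: str) -> str:
    """Extract a chemical symbol from a CIF type string like ``'C'``, ``'O1-'`` or ``'Fe2+'``."""
    stripped = "".join(ch for ch in raw if ch.isalpha())
    if not stripped:
        raise PixkitError(f"cannot extract element symbol from {raw!r}")
    for length in (2, 1):
        candidate = stripped[:length].capitalize()
        if candidate in ATOMIC_NUMBER:
            return candidate
    raise PixkitError(f"unrecognized element symbol {raw!r}")


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASS[element]
    except KeyError:
        raise PixkitError(f"no atomic mass for element {element!r}") from None


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADIUS[element]
    except KeyError:
        raise PixkitError(f"no covalent radius for element {element!r}") from None


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    if table is not None and element in table:
        return table[element]
    return VDW_RADIUS.get(element, DEFAULT_VDW_RADIUS)
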