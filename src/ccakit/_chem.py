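"""Element tables shared across perception, editing and fixture building.

Covalent radii are classic single-bond radii; reference bond lengths are
canonical values for order classification of perceived bonds. Both are fixed
built-ins so that perception is transparent and testable.
"""

from __future__ import annotations

# single-bond covalent radii, Angstrom
COVALENT_RADII: dict[str, float] = {
    "H": 0.37, "B": 0.82, "C": 0.77, "N": 0.75, "O": 0.73, "F": 0.71,
    "SI": 1.11, "P": 1.10, "S": 1.05, "CL": 0.99, "SE": 1.17, "BR": 1.14,
    "I": 1.33,
    # metals
    "LI": 1.34, "NA": 1.54, "MG": 1.30, "K": 1.96, "CA": 1.74,
    "MN": 1.39, "FE": 1.25, "CO": 1.26, "NI": 1.21, "CU": 1.38, "ZN": 1.31,
    "CD": 1.48, "HG": 1.49,
}

METALS = frozenset({
    "LI", "NA", "MG", "K", "CA", "MN", "FE", "CO", "NI", "CU", "ZN",
    "CD", "HG",
})

#: distance tolerance added to the radius sum for covalent-bond perception (A)
BOND_TOLERANCE = 0.40
#: metal-to-N/O/S contacts within this distance are coordination, never bonds
METAL_CONTACT_CUTOFF = 3.0

# reference bond lengths (A) per unordered element pair, keyed by order.
# Used for nearest-reference bond-order classification; pairs absent from the
# table are always classified single.
_REF = {
    ("C", "C"): {"single": 1.54, "double": 1.34, "triple": 1.20},
    ("C", "N"): {"single": 1.47, "double": 1.29, "triple": 1.16},
    ("C", "O"): {"single": 1.43, "double": 1.22},
    ("C", "S"): {"single": 1.82, "double": 1.60},
    ("N", "N"): {"single": 1.45, "double": 1.25, "triple": 1.10},
    ("N", "O"): {"single": 1.40, "double": 1.21},
    ("O", "O"): {"single": 1.48},
    ("O", "S"): {"single": 1.58, "double": 1.45},
    ("O", "P"): {"single": 1.63, "double": 1.50},
    ("S", "S"): {"single": 2.05, "double": 1.88},
}

# standard valences for the implicit-hydrogen model; multiple entries mean
# the smallest valence accommodating the explicit bond-order sum is used
STANDARD_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,), "B": (3,), "C": (4,), "N": (3,), "O": (2,), "F": (1,),
    "P": (3, 5), "S": (2, 4, 6), "CL": (1,), "BR": (1,), "I": (1,),
    "SE": (2, 4, 6), "SI": (4,),
}

ORDER_VALUE = {"single": 1, "double": 2, "triple": 3, "unspecified": 1,
               "aromatic": 1.5}

STANDARD_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})

WATERS = frozenset({"HOH", "DOD", "WAT"})


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no covalent radius for element {element!r}") from None


def is_metal(element: str) -> bool:
    return element.upper() in METALS


def reference_lengths(elem1: str, elem2: str) -> dict[str, float]:
    """Reference lengths for an element pair; empty dict when untabulated."""
    e1, e2 = sorted((elem1.capitalize(), elem2.capitalize()))
    return _REF.get((e1, e2), {})


def classify_order(elem1: str, elem2: str, distance: float) -> str:
    """Bond order whose reference length is nearest the observed distance."""
    refs = reference_lengths(elem1, elem2)
    if not refs:
        return "single"
    return min(refs, key=lambda o: abs(refs[o] - distance))


def valence_for(element: str, charge: int = 0) -> tuple[int, ...]:
    """Allowed total valences (bond-order sum + implicit H) for an element.

    Charge adjustments follow the usual organic conventions: a positive
    charge on N raises its valence to 4, a negative charge on O lowers it
    to 1, and in general each unit of charge shifts the valence by one in
    the direction that conserves the electron count.
    """
    base = STANDARD_VALENCES.get(element.upper())
    if base is None:
        return ()
    if charge == 0:
        return base
    if element.upper() in ("N", "P"):
        return tuple(max(0, v + charge) for v in base)
    return tuple(max(0, v - abs(charge)) for v in base)
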