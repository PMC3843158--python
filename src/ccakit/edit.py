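"""Programmatic component editing: atoms, bond orders, descriptors, commit.

Definitions follow a heavy-atom + implicit-hydrogen convention: each atom's
hydrogen count is whatever brings its bond-order sum up to the standard
valence for its element and formal charge (C 4, N 3, O 2, S 2/4/6, P 3/5 by
default, overridable). Every edit re-derives the implicit hydrogens and the
Hill-order formula, and an edit that would overflow an element's maximum
valence is rejected outright.
"""

from __future__ import annotations

import copy

import numpy as np

from ._chem import ORDER_VALUE, valence_for
from .ccdio import AtomDef, BondDef, ComponentDefinition, Dictionary

__all__ = [
    "implicit_hydrogens", "compute_formula", "add_atom", "set_bond_order",
    "recompute_descriptors", "commit_definition", "apply_edit_script",
]


def _bond_order_sum(comp: ComponentDefinition, atom_name: str) -> float:
    total = 0.0
    for b in comp.bonds:
        if atom_name in (b.atom1, b.atom2):
            total += 1.5 if b.aromatic else ORDER_VALUE[b.order]
    return total


def implicit_hydrogens(comp: ComponentDefinition, atom_name: str,
                       valences: dict | None = None) -> int:
    """Implicit-H count at one atom under the standard-valence model.

    Raises ValueError when the explicit bond-order sum exceeds every allowed
    valence for the element (a valence overflow).
    """
    atom = comp.atom(atom_name)
    if atom.element.upper() == "H":
        return 0
    allowed = (valences or {}).get(atom.element.upper()) or \
        valence_for(atom.element, atom.charge)
    if not allowed:  # metals and other elements outside the valence model
        return 0
    # explicit hydrogens bonded to this atom consume implicit slots
    explicit_h = sum(
        1 for b in comp.bonds
        if (b.atom1 == atom_name and comp.atom(b.atom2).element.upper() == "H")
        or (b.atom2 == atom_name and comp.atom(b.atom1).element.upper() == "H"))
    # explicit H bonds already contribute 1 each to the bond-order sum, so
    # the subtraction below automatically decrements the implicit count
    _ = explicit_h
    bsum_int = int(round(_bond_order_sum(comp, atom_name)))
    for v in sorted(allowed):
        if bsum_int <= v:
            return int(v - bsum_int)
    raise ValueError(
        f"{comp.comp_id}: valence overflow at {atom_name} "
        f"(bond-order sum {bsum_int}, allowed {sorted(allowed)})")


def compute_formula(comp: ComponentDefinition,
                    valences: dict | None = None) -> str:
    """Hill-order formula including implicit hydrogens: C first, H second,
    remaining elements alphabetically (all alphabetical when no carbon)."""
    counts: dict[str, int] = {}
    n_h = 0
    for a in comp.atoms:
        el = a.element.capitalize()
        if el == "H":
            n_h += 1
            continue
        counts[el] = counts.get(el, 0) + 1
        n_h += implicit_hydrogens(comp, a.name, valences)
    ordered: list[tuple[str, int]] = []
    if "C" in counts:
        ordered.append(("C", counts.pop("C")))
        if n_h:
            ordered.append(("H", n_h))
        ordered.extend(sorted(counts.items()))
    else:
        if n_h:
            counts["H"] = n_h
        ordered.extend(sorted(counts.items()))
    return " ".join(el if n == 1 else f"{el}{n}" for el, n in ordered)


def _validate_valences(comp: ComponentDefinition,
                       valences: dict | None = None) -> None:
    for a in comp.atoms:
        implicit_hydrogens(comp, a.name, valences)  # raises on overflow


def _placeholder_position(comp: ComponentDefinition,
                          anchor: str) -> tuple[float, float, float]:
    """Approximate ideal position for a newly added atom: 1.5 A from its
    anchor, opposite the mean direction of the anchor's existing neighbors
    (tetrahedral/trigonal completion); along +x for a bare anchor."""
    anchor_atom = comp.atom(anchor)
    origin = np.asarray(anchor_atom.xyz)
    nbrs = []
    for b in comp.bonds:
        if b.atom1 == anchor:
            nbrs.append(np.asarray(comp.atom(b.atom2).xyz))
        elif b.atom2 == anchor:
            nbrs.append(np.asarray(comp.atom(b.atom1).xyz))
    if not nbrs:
        direction = np.array([1.0, 0.0, 0.0])
    else:
        mean = np.mean([n - origin for n in nbrs], axis=0)
        norm = float(np.linalg.norm(mean))
        direction = (np.array([1.0, 0.0, 0.0]) if norm < 1e-6
                     else -mean / norm)
    return tuple(np.round(origin + 1.5 * direction, 3))


def add_atom(comp: ComponentDefinition, name: str, element: str,
             bonded_to: str, order: str = "single",
             valences: dict | None = None) -> ComponentDefinition:
    """Add an atom bonded to an existing anchor; recompute H and formula.

    The new atom gets a placeholder idealized position from local geometry —
    edited definitions carry approximate, not re-embedded, coordinates.
    """
    if any(a.name == name for a in comp.atoms):
        raise ValueError(f"{comp.comp_id}: atom {name!r} already exists")
    comp.atom(bonded_to)  # raises if missing
    new = copy.deepcopy(comp)
    new.atoms.append(AtomDef(name=name, element=element.capitalize(),
                             xyz=_placeholder_position(comp, bonded_to)))
    new.bonds.append(BondDef(atom1=bonded_to, atom2=name, order=order))
    _validate_valences(new, valences)
    return recompute_descriptors(new, valences)


def set_bond_order(comp: ComponentDefinition, a1: str, a2: str,
                   new_order: str,
                   valences: dict | None = None) -> ComponentDefinition:
    """Replace one bond's order; implicit H at both ends are re-derived."""
    new = copy.deepcopy(comp)
    for i, b in enumerate(new.bonds):
        if {b.atom1, b.atom2} == {a1, a2}:
            new.bonds[i] = BondDef(atom1=b.atom1, atom2=b.atom2,
                                   order=new_order, aromatic=b.aromatic)
            _validate_valences(new, valences)
            return recompute_descriptors(new, valences)
    raise ValueError(f"{comp.comp_id}: no bond {a1}-{a2}")


def recompute_descriptors(comp: ComponentDefinition,
                          valences: dict | None = None,
                          ) -> ComponentDefinition:
    """Refresh formula, aromatic flags and stereo flags from the graph.

    Idempotent and invariant under atom reordering: a second call changes
    nothing.
    """
    from .perception import graph_from_definition

    new = copy.deepcopy(comp)
    new.formula = compute_formula(new, valences)
    # drop stereo flags that no longer mark a valid center, then take
    # aromatic flags from perception over stored orders
    probe = copy.deepcopy(new)
    for i, a in enumerate(probe.atoms):
        heavy_nbrs = sum(
            1 for b in probe.bonds
            if (b.atom1 == a.name
                and probe.atom(b.atom2).element.upper() != "H")
            or (b.atom2 == a.name
                and probe.atom(b.atom1).element.upper() != "H"))
        if a.stereo != "none" and heavy_nbrs < 3:
            probe.atoms[i] = AtomDef(
                name=a.name, element=a.element, charge=a.charge,
                aromatic=a.aromatic, stereo="none", xyz=a.xyz,
                leaving=a.leaving)
    # aromatic perception from orders (ignore any stale stored flags)
    stripped = copy.deepcopy(probe)
    stripped.atoms = [AtomDef(name=a.name, element=a.element, charge=a.charge,
                              aromatic=False, stereo=a.stereo, xyz=a.xyz,
                              leaving=a.leaving) for a in stripped.atoms]
    stripped.bonds = [BondDef(atom1=b.atom1, atom2=b.atom2, order=b.order,
                              aromatic=False) for b in stripped.bonds]
    g = graph_from_definition(stripped)
    new.atoms = [AtomDef(name=a.name, element=a.element, charge=a.charge,
                         aromatic=bool(g.g.nodes[a.name]["aromatic"]),
                         stereo=a.stereo, xyz=a.xyz, leaving=a.leaving)
                 for a in probe.atoms]
    new.bonds = [BondDef(atom1=b.atom1, atom2=b.atom2, order=b.order,
                         aromatic=bool(g.g.edges[b.atom1, b.atom2].get(
                             "aromatic", False)))
                 for b in probe.bonds]
    return new


def commit_definition(d: Dictionary, new_def: ComponentDefinition,
                      ) -> Dictionary:
    """Redundancy-check then add; duplicate chemistry or id is an error."""
    from .matching import redundancy_check

    new_def.validate()
    if new_def.comp_id in d:
        raise ValueError(f"comp_id {new_def.comp_id} already in dictionary")
    duplicates = redundancy_check(new_def, d)
    if duplicates:
        raise ValueError(
            f"definition {new_def.comp_id} duplicates existing component(s) "
            f"{', '.join(duplicates)}")
    d.add(new_def)
    return d


def apply_edit_script(d: Dictionary, comp: ComponentDefinition,
                      lines: list[str]) -> tuple[Dictionary,
                                                 ComponentDefinition]:
    """Line-oriented edit commands for reproducible sessions.

    Commands: ``addatom NAME ELEMENT ANCHOR [ORDER]``,
    ``order A1 A2 NEW_ORDER``, ``bond A1 A2 [ORDER]``, ``commit``.
    """
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        cmd, args = tokens[0].lower(), tokens[1:]
        try:
            if cmd == "addatom":
                name, element, anchor = args[:3]
                order = args[3] if len(args) > 3 else "single"
                comp = add_atom(comp, name, element, anchor, order)
            elif cmd == "order":
                comp = set_bond_order(comp, args[0], args[1], args[2])
            elif cmd == "bond":
                order = args[2] if len(args) > 2 else "single"
                new = copy.deepcopy(comp)
                new.bonds.append(BondDef(atom1=args[0], atom2=args[1],
                                         order=order))
                _validate_valences(new)
                comp = recompute_descriptors(new)
            elif cmd == "commit":
                commit_definition(d, comp)
            else:
                raise ValueError(f"unknown command {cmd!r}")
        except (ValueError, KeyError, IndexError) as exc:
            raise ValueError(f"edit script line {lineno}: {exc}") from exc
    return d, comp
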