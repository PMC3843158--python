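"""Covalent-linkage detection and leaving-group augmentation.

Small molecules in structure entries are frequently bound covalently to the
macromolecule (glycosylation being the canonical case) or to other small
molecules. The attachment consumes a substituent of the free component —
e.g. the anomeric hydroxyl of a pyranose — so the observed instance lacks
the atom that makes the attachment carbon a defined stereocenter. Capping
restores a surrogate: an -OH along the former partner direction for a carbon
attachment, an -H for nitrogen or oxygen, after which re-perception yields a
defined handedness at the attachment center and the instance matches its
free-form definition atom for atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _chem
from .ccdio import StructureEntry

__all__ = ["Linkage", "detect_linkages", "add_leaving_group"]

#: cap bond lengths, Angstrom
CAP_C_O = 1.43
CAP_X_H = 1.01


@dataclass(frozen=True)
class Linkage:
    instance_atom: str
    partner_chain: str
    partner_seqnum: int
    partner_icode: str
    partner_comp_id: str
    partner_atom: str
    partner_xyz: tuple[float, float, float]
    distance: float
    kind: str  # "covalent" | "coordination"

    def to_record(self) -> dict:
        """struct_conn-style record."""
        return {
            "conn_type": "covale" if self.kind == "covalent" else "metalc",
            "atom_1": self.instance_atom,
            "chain_2": self.partner_chain,
            "seq_2": self.partner_seqnum,
            "comp_2": self.partner_comp_id,
            "atom_2": self.partner_atom,
            "dist": round(self.distance, 3),
        }


def detect_linkages(inst, entry: StructureEntry, config=None) -> list[Linkage]:
    """Inter-residue contacts of an instance, classified covalent (within the
    covalent-radius rule) or coordination (metal to N/O/S within cutoff)."""
    from .perception import DEFAULT_CONFIG

    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    own = set(inst.residue_keys)
    links: list[Linkage] = []
    g = inst.graph
    for name in sorted(g.heavy_atoms()):
        if g.g.nodes[name].get("cap"):
            continue
        xyz = g.xyz(name)
        el = g.element(name)
        for res in entry.residues:
            if res.key in own:
                continue
            for a in res.atoms:
                if a.element.upper() == "H":
                    continue
                d = float(np.linalg.norm(xyz - np.asarray(a.xyz)))
                if d > max(cfg["metal_contact_cutoff"], 3.5):
                    continue
                if _chem.is_metal(el) or _chem.is_metal(a.element):
                    other = a.element if _chem.is_metal(el) else el
                    if other.upper() in ("N", "O", "S") and \
                            d <= cfg["metal_contact_cutoff"]:
                        links.append(Linkage(
                            name, res.chain, res.seqnum, res.icode,
                            res.comp_id, a.name, tuple(a.xyz), d,
                            "coordination"))
                    continue
                rsum = (_chem.covalent_radius(el)
                        + _chem.covalent_radius(a.element)
                        + cfg["bond_tolerance"])
                if d <= rsum:
                    links.append(Linkage(
                        name, res.chain, res.seqnum, res.icode,
                        res.comp_id, a.name, tuple(a.xyz), d, "covalent"))
    return links


def add_leaving_group(inst, links: list[Linkage], config=None):
    """Cap each covalent attachment so stereochemistry becomes determinable.

    For every covalent linkage a surrogate atom is appended along the unit
    vector from the attachment atom toward the former partner: an oxygen at
    1.43 A when the attachment atom is carbon (a leaving hydroxyl with
    implicit H), a hydrogen at 1.01 A when it is nitrogen or oxygen. No
    existing coordinate moves — capping only appends. The capped instance is
    re-perceived, which makes the attachment center's handedness defined
    (unless its geometry is genuinely planar, in which case sp2 still wins
    and the center stays non-chiral).
    """
    from .matching import ComponentInstance
    from .perception import perceive_all

    covalent = [l for l in links if l.kind == "covalent"]
    if not covalent:
        return inst
    g = inst.graph
    atoms = [(n, g.element(n), tuple(g.xyz(n))) for n in g.atoms()]
    existing = {n for n, _, _ in atoms}
    cap_atoms = list(inst.cap_atoms)
    for i, link in enumerate(covalent, start=1):
        if link.instance_atom not in existing:
            raise KeyError(
                f"attachment atom {link.instance_atom!r} not in instance")
        el = g.element(link.instance_atom).upper()
        if el == "C":
            if len(g.heavy_neighbors(link.instance_atom)) >= 4:
                raise ValueError(
                    f"attachment atom {link.instance_atom} already at full "
                    "valence")
            cap_el, length = "O", CAP_C_O
        elif el in ("N", "O"):
            cap_el, length = "H", CAP_X_H
        else:
            continue  # no default cap for other attachment elements
        origin = np.asarray(g.xyz(link.instance_atom))
        direction = np.asarray(link.partner_xyz) - origin
        norm = float(np.linalg.norm(direction))
        if norm == 0.0:
            raise ValueError("degenerate linkage geometry")
        pos = origin + direction / norm * length
        cap_name = f"{cap_el}CAP{i}"
        while cap_name in existing:
            cap_name += "X"
        atoms.append((cap_name, cap_el, tuple(pos)))
        existing.add(cap_name)
        cap_atoms.append(cap_name)
    capped = ComponentInstance(
        chain=inst.chain, seqnum=inst.seqnum, icode=inst.icode,
        comp_id=inst.comp_id, residue_keys=list(inst.residue_keys),
        group_id=inst.group_id, linkages=list(inst.linkages),
        cap_atoms=cap_atoms)
    capped.graph = perceive_all(atoms, config)
    for name in cap_atoms:
        if name in capped.graph.g.nodes:
            capped.graph.g.nodes[name]["cap"] = True
    return capped
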