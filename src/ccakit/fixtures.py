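"""Synthetic toy dictionary and synthetic structure entries.

The toy dictionary stands in for a real component dictionary: ~15 hand-built
definitions (amino acids, two anomeric pyranoses and an N-acetyl pair, a
morpholine-ethanesulfonic acid, aromatic and saturated rings, a zinc ion,
the lisinopril connection table and a triglycine parent) whose idealized
coordinates are generated from ideal internal coordinates — tetrahedral
109.47 deg, trigonal 120 deg angles, canonical single/double reference bond
lengths — so geometric perception of every definition is unambiguous and
reproduces its stored graph exactly.

Entries are assembled from perturbable copies of those definitions placed on
a coarse grid. Each perturbation is designed to degrade exactly one
composite-score category (or one triage outcome):

============================  =========================================
perturbation                   intended effect
============================  =========================================
flatten_chiral(atom)           chiral-center count drops (sp2 overrides)
invert_parity(atom)            handedness drops, center count intact
change_bond_order(a1, a2)      bond-order category drops
rename_atoms                   nomenclature differs, chemistry intact
relabel_id(new)                status close match, all categories 100
delete_atom(atom)              heavy-atom count drops (subgraph fallback)
link_to_polymer(atom)          covalent attachment consumes a substituent
============================  =========================================
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .ccdio import (AtomDef, BondDef, ComponentDefinition, Dictionary,
                    EntryAtom, Residue, StructureEntry)

__all__ = ["make_toy_dictionary", "make_entry", "PERTURBATIONS"]

TET = 109.471  # tetrahedral angle, degrees

# canonical bond lengths used by the builder (match the perception table)
L_CC, L_CN, L_CO, L_CdO, L_CS, L_SO, L_SdO = 1.54, 1.47, 1.43, 1.22, 1.82, 1.58, 1.45
L_RING_AROM = 1.39


# ---------------------------------------------------------------------------
# geometry helpers

def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def place_atom(a, b, c, bond: float, angle: float, dihedral: float):
    """NeRF placement: position D with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = dihedral (degrees)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang, dih = math.radians(angle), math.radians(dihedral)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(dih),
                  bond * math.sin(ang) * math.sin(dih)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def sp3_slots(center, neighbors, angle: float = TET) -> list[np.ndarray]:
    """Unit directions completing an ideal tetrahedron around ``center``
    given 1-3 known neighbor positions."""
    center = np.asarray(center, float)
    units = [_unit(np.asarray(n) - center) for n in neighbors]
    ca = math.cos(math.radians(angle))
    if len(units) == 3:
        return [-_unit(sum(units))]
    if len(units) == 2:
        u1, u2 = units
        b = -_unit(u1 + u2)
        p = _unit(np.cross(u1, u2))
        alpha = ca / float(np.dot(b, u1))
        beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
        return [_unit(alpha * b + beta * p), _unit(alpha * b - beta * p)]
    u = units[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = _unit(np.cross(u, ref))
    q = np.cross(u, p)
    sa = math.sqrt(1.0 - ca * ca)
    return [_unit(ca * u + sa * (math.cos(t) * p + math.sin(t) * q))
            for t in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)]


def chair_ring(bond: float = 1.53, n: int = 6):
    """Ideal chair: six positions with exact bond length and tetrahedral
    ring angles."""
    assert n == 6

    def angle_at(z):
        r = math.sqrt(bond * bond - 4 * z * z)
        pts = [np.array([r * math.cos(k * math.pi / 3),
                         r * math.sin(k * math.pi / 3),
                         z if k % 2 == 0 else -z]) for k in range(3)]
        v1, v2 = pts[0] - pts[1], pts[2] - pts[1]
        return math.degrees(math.acos(
            float(np.dot(v1, v2)) / (bond * bond))) - TET

    z = brentq(angle_at, 0.05, bond / 2 - 1e-6)
    r = math.sqrt(bond * bond - 4 * z * z)
    return [np.array([r * math.cos(k * math.pi / 3),
                      r * math.sin(k * math.pi / 3),
                      z if k % 2 == 0 else -z]) for k in range(6)]


def hexagon(bond: float = L_RING_AROM):
    return [np.array([bond * math.cos(k * math.pi / 3),
                      bond * math.sin(k * math.pi / 3), 0.0])
            for k in range(6)]


def pentagon(bond: float = 1.50):
    rad = bond / (2 * math.sin(math.pi / 5))
    return [np.array([rad * math.cos(2 * k * math.pi / 5),
                      rad * math.sin(2 * k * math.pi / 5), 0.0])
            for k in range(5)]


# ---------------------------------------------------------------------------
# definition assembly

class _Builder:
    """Accumulates atoms/bonds with coordinates, then emits a definition."""

    def __init__(self, comp_id: str, name: str = ""):
        self.comp_id, self.name = comp_id, name
        self.atoms: list[tuple[str, str, np.ndarray]] = []
        self.bonds: list[tuple[str, str, str, bool]] = []
        self.pos: dict[str, np.ndarray] = {}
        self.charges: dict[str, int] = {}
        self.leaving: set[str] = set()
        self.aromatic_atoms: set[str] = set()

    def atom(self, name, element, xyz, charge=0):
        xyz = np.asarray(xyz, float)
        self.atoms.append((name, element, xyz))
        self.pos[name] = xyz
        if charge:
            self.charges[name] = charge

    def bond(self, a, b, order="single", aromatic=False):
        self.bonds.append((a, b, order, aromatic))
        if aromatic:
            self.aromatic_atoms.update((a, b))

    def nbr_pos(self, name):
        out = []
        for a, b, _, _ in self.bonds:
            if a == name:
                out.append(self.pos[b])
            elif b == name:
                out.append(self.pos[a])
        return out

    def build(self, stereocenters: tuple[str, ...] = ()) -> ComponentDefinition:
        from .edit import compute_formula
        from .perception import graph_from_definition

        comp = ComponentDefinition(comp_id=self.comp_id, name=self.name)
        for name, element, xyz in self.atoms:
            comp.atoms.append(AtomDef(
                name=name, element=element.capitalize(),
                charge=self.charges.get(name, 0),
                aromatic=name in self.aromatic_atoms,
                stereo="S" if name in stereocenters else "none",
                xyz=tuple(np.round(xyz, 3)),
                leaving=name in self.leaving))
        for a, b, order, aromatic in self.bonds:
            comp.bonds.append(BondDef(atom1=a, atom2=b, order=order,
                                      aromatic=aromatic))
        comp.formula = compute_formula(comp)
        if stereocenters:
            # relabel each flag from its geometric parity (R: +1, S: -1);
            # the letter is a parity tag, not a CIP assignment
            g = graph_from_definition(comp)
            comp.atoms = [
                AtomDef(name=a.name, element=a.element, charge=a.charge,
                        aromatic=a.aromatic,
                        stereo=("R" if g.g.nodes[a.name]["parity"] > 0
                                else "S") if a.stereo != "none" else "none",
                        xyz=a.xyz, leaving=a.leaving)
                for a in comp.atoms]
        comp.validate()
        return comp


def _amino_acid(comp_id: str, name: str, side_chain) -> ComponentDefinition:
    """Free neutral amino-acid skeleton N-CA-C(=O)-OXT; ``side_chain(b, slots)``
    adds whatever hangs off CA using the two free tetrahedral slots."""
    b = _Builder(comp_id, name)
    ca = np.zeros(3)
    b.atom("CA", "C", ca)
    b.atom("N", "N", ca + np.array([L_CN, 0.0, 0.0]))
    b.bond("N", "CA")
    slots = sp3_slots(ca, [b.pos["N"]])
    c_pos = ca + L_CC * slots[0]
    b.atom("C", "C", c_pos)
    b.bond("CA", "C")
    # trigonal carboxyl in the plane defined via NeRF from N-CA-C
    o = place_atom(b.pos["N"], ca, c_pos, L_CdO, 120.0, 0.0)
    oxt = place_atom(b.pos["N"], ca, c_pos, L_CO, 120.0, 180.0)
    b.atom("O", "O", o)
    b.atom("OXT", "O", oxt)
    b.bond("C", "O", "double")
    b.bond("C", "OXT")
    b.leaving.add("OXT")
    if side_chain is not None:
        side_chain(b, [ca + s for s in sp3_slots(ca, [b.pos["N"], c_pos])])
    return b


def _make_gly():
    return _amino_acid("GLY", "glycine", None).build()


def _make_ala():
    def side(b, slots):
        b.atom("CB", "C", b.pos["CA"] + L_CC * _unit(slots[0] - b.pos["CA"]))
        b.bond("CA", "CB")
    return _amino_acid("ALA", "alanine", side).build(stereocenters=("CA",))


def _make_lys():
    def side(b, slots):
        prev2, prev1 = b.pos["N"], b.pos["CA"]
        chain = [("CB", "C", L_CC), ("CG", "C", L_CC), ("CD", "C", L_CC),
                 ("CE", "C", L_CC), ("NZ", "N", L_CN)]
        pos = b.pos["CA"] + L_CC * _unit(slots[0] - b.pos["CA"])
        b.atom("CB", "C", pos)
        b.bond("CA", "CB")
        prev2, prev1, cur = b.pos["N"], b.pos["CA"], pos
        last = "CB"
        for name, el, length in chain[1:]:
            nxt = place_atom(prev2, prev1, cur, length, TET, 180.0)
            b.atom(name, el, nxt)
            b.bond(last, name)
            prev2, prev1, cur, last = prev1, cur, nxt, name
    return _amino_acid("LYS", "lysine", side).build(stereocenters=("CA",))


def _make_pro():
    b = _Builder("PRO", "proline")
    ring = pentagon(1.50)
    names = ["N", "CA", "CB", "CG", "CD"]
    for name, p in zip(names, ring):
        b.atom(name, "N" if name == "N" else "C", p)
    for i in range(5):
        b.bond(names[i], names[(i + 1) % 5])
    # exocyclic carboxyl off CA, out of the ring plane
    slots = sp3_slots(b.pos["CA"], [b.pos["N"], b.pos["CB"]])
    c_pos = b.pos["CA"] + L_CC * slots[0]
    b.atom("C", "C", c_pos)
    b.bond("CA", "C")
    o = place_atom(b.pos["N"], b.pos["CA"], c_pos, L_CdO, 120.0, 0.0)
    oxt = place_atom(b.pos["N"], b.pos["CA"], c_pos, L_CO, 120.0, 180.0)
    b.atom("O", "O", o)
    b.atom("OXT", "O", oxt)
    b.bond("C", "O", "double")
    b.bond("C", "OXT")
    b.leaving.add("OXT")
    return b.build(stereocenters=("CA",))


def _pyranose_builder(comp_id: str, name: str, c2_group: str,
                      o1_slot: int) -> _Builder:
    """Six-membered sugar ring O5-C1-...-C5 with hydroxyl (or acetamido)
    substituents; ``o1_slot`` picks which tetrahedral slot at C1 holds the
    anomeric O1 (0/1 distinguish the two anomers)."""
    b = _Builder(comp_id, name)
    ring = chair_ring(L_CC)
    ring_names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    for rn, p in zip(ring_names, ring):
        b.atom(rn, "O" if rn == "O5" else "C", p)
    for i in range(6):
        b.bond(ring_names[i], ring_names[(i + 1) % 6])

    def slots_at(rn):
        i = ring_names.index(rn)
        left = b.pos[ring_names[(i - 1) % 6]]
        right = b.pos[ring_names[(i + 1) % 6]]
        raw = sp3_slots(b.pos[rn], [left, right])
        return sorted(raw, key=lambda s: -s[2])  # deterministic up/down

    # anomeric hydroxyl
    s1 = slots_at("C1")
    b.atom("O1", "O", b.pos["C1"] + L_CO * s1[o1_slot])
    b.bond("C1", "O1")
    b.leaving.add("O1")
    # C2 substituent: hydroxyl or N-acetyl
    s2 = slots_at("C2")
    if c2_group == "OH":
        b.atom("O2", "O", b.pos["C2"] + L_CO * s2[0])
        b.bond("C2", "O2")
    else:  # acetamido
        n2 = b.pos["C2"] + L_CN * s2[0]
        b.atom("N2", "N", n2)
        b.bond("C2", "N2")
        c7 = place_atom(b.pos["C1"], b.pos["C2"], n2, L_CN, TET, 90.0)
        b.atom("C7", "C", c7)
        b.bond("N2", "C7")
        o7 = place_atom(b.pos["C2"], n2, c7, L_CdO, 120.0, 0.0)
        c8 = place_atom(b.pos["C2"], n2, c7, L_CC, 120.0, 180.0)
        b.atom("O7", "O", o7)
        b.atom("C8", "C", c8)
        b.bond("C7", "O7", "double")
        b.bond("C7", "C8")
    for rn, on in (("C3", "O3"), ("C4", "O4")):
        s = slots_at(rn)
        b.atom(on, "O", b.pos[rn] + L_CO * s[0])
        b.bond(rn, on)
    # exocyclic CH2-OH at C5
    s5 = slots_at("C5")
    c6 = b.pos["C5"] + L_CC * s5[0]
    b.atom("C6", "C", c6)
    b.bond("C5", "C6")
    o6 = place_atom(b.pos["O5"], b.pos["C5"], c6, L_CO, TET, 180.0)
    b.atom("O6", "O", o6)
    b.bond("C6", "O6")
    return b


_SUGAR_CENTERS = ("C1", "C2", "C3", "C4", "C5")


def _make_man():
    return _pyranose_builder("MAN", "toy alpha-pyranose", "OH", 0).build(
        stereocenters=_SUGAR_CENTERS)


def _make_nag():
    return _pyranose_builder("NAG", "toy 2-acetamido pyranose, beta anomer",
                             "NAc", 0).build(stereocenters=_SUGAR_CENTERS)


def _make_ndg():
    return _pyranose_builder("NDG", "toy 2-acetamido pyranose, alpha anomer",
                             "NAc", 1).build(stereocenters=_SUGAR_CENTERS)


def _make_mes():
    b = _Builder("MES", "toy morpholine-ethanesulfonic acid")
    ring = chair_ring(1.48)
    names = ["O1", "C2", "C3", "N4", "C5", "C6"]
    for rn, p in zip(names, ring):
        b.atom(rn, rn[0], p)
    for i in range(6):
        b.bond(names[i], names[(i + 1) % 6])
    slots = sorted(sp3_slots(b.pos["N4"], [b.pos["C3"], b.pos["C5"]]),
                   key=lambda s: -s[2])
    c7 = b.pos["N4"] + L_CN * slots[0]
    b.atom("C7", "C", c7)
    b.bond("N4", "C7")
    c8 = place_atom(b.pos["C3"], b.pos["N4"], c7, L_CC, TET, 180.0)
    b.atom("C8", "C", c8)
    b.bond("C7", "C8")
    s1 = place_atom(b.pos["N4"], c7, c8, L_CS, TET, 180.0)
    b.atom("S1", "S", s1)
    b.bond("C8", "S1")
    o1s = place_atom(c7, c8, s1, L_SdO, TET, 60.0)
    o2s = place_atom(c7, c8, s1, L_SdO, TET, 180.0)
    o3s = place_atom(c7, c8, s1, L_SO, TET, 300.0)
    b.atom("O1S", "O", o1s)
    b.atom("O2S", "O", o2s)
    b.atom("O3S", "O", o3s)
    b.bond("S1", "O1S", "double")
    b.bond("S1", "O2S", "double")
    b.bond("S1", "O3S")
    return b.build()


def _aromatic_hexagon(comp_id, name, first_element):
    b = _Builder(comp_id, name)
    names = []
    for k, p in enumerate(hexagon()):
        el = first_element if k == 0 else "C"
        an = f"{el}{k + 1}"
        names.append(an)
        b.atom(an, el, p)
    for i in range(6):
        b.bond(names[i], names[(i + 1) % 6],
               "double" if i % 2 == 0 else "single", aromatic=True)
    return b.build()


def _make_bnz():
    return _aromatic_hexagon("BNZ", "toy benzene", "C")


def _make_pyr():
    return _aromatic_hexagon("PYR", "toy pyridine", "N")


def _make_chx():
    b = _Builder("CHX", "toy cyclohexane")
    for k, p in enumerate(chair_ring(L_CC)):
        b.atom(f"C{k + 1}", "C", p)
    for i in range(6):
        b.bond(f"C{i + 1}", f"C{(i + 1) % 6 + 1}")
    return b.build()


def _make_zn():
    b = _Builder("ZN", "zinc ion")
    b.atom("ZN", "Zn", np.zeros(3), charge=2)
    return b.build()


def _regular_ring(v0, radial, normal, n: int, side: float):
    """Regular n-gon with vertex 0 at ``v0``, lying in the plane orthogonal
    to ``normal``; ``radial`` is the in-plane unit vector from vertex 0
    toward the ring center."""
    rad = side / (2 * math.sin(math.pi / n))
    center = np.asarray(v0) + rad * radial
    t = _unit(np.cross(normal, radial))
    return [center + rad * (math.cos(math.pi + 2 * math.pi * k / n) * radial
                            + math.sin(math.pi + 2 * math.pi * k / n) * t)
            for k in range(n)]


def _phenyl(b: _Builder, attach: str, prev2, prev1, prefix="CP"):
    """Grow a benzene ring off ``attach`` (prev2-prev1-attach set the frame);
    the ring's para axis continues the attachment direction."""
    c1 = place_atom(prev2, prev1, b.pos[attach], 1.50, TET, 180.0)
    b.atom(f"{prefix}1", "C", c1)
    b.bond(attach, f"{prefix}1")
    radial = _unit(c1 - b.pos[attach])
    normal = _unit(np.cross(radial, b.pos[attach] - np.asarray(prev1)))
    verts = _regular_ring(c1, radial, normal, 6, L_RING_AROM)
    ring = [f"{prefix}{i}" for i in range(1, 7)]
    for rn, v in zip(ring[1:], verts[1:]):
        b.atom(rn, "C", v)
    for i in range(6):
        b.bond(ring[i], ring[(i + 1) % 6],
               "double" if i % 2 == 0 else "single", aromatic=True)


def _clt_core(b: _Builder, with_hydroxyl: bool):
    """Shared skeleton: HOOC-C2(H)(X)-C3H2-C4H2-phenyl; X is the anomeric-
    style position — hydroxyl O3 in the free acid, the amine N in the
    condensed parent."""
    c2 = np.zeros(3)
    b.atom("C2", "C", c2)
    c1 = c2 + np.array([L_CC, 0.0, 0.0])
    b.atom("C1", "C", c1)
    b.bond("C1", "C2")
    slots = sp3_slots(c2, [c1])
    c3 = c2 + L_CC * slots[0]
    b.atom("C3", "C", c3)
    b.bond("C2", "C3")
    if with_hydroxyl:
        b.atom("O3", "O", c2 + L_CO * slots[1])
        b.bond("C2", "O3")
        b.leaving.add("O3")
    # carboxyl on C1, trigonal
    o1 = place_atom(c3, c2, c1, L_CdO, 120.0, 0.0)
    o2 = place_atom(c3, c2, c1, L_CO, 120.0, 180.0)
    b.atom("O1", "O", o1)
    b.atom("O2", "O", o2)
    b.bond("C1", "O1", "double")
    b.bond("C1", "O2")
    c4 = place_atom(c1, c2, c3, L_CC, TET, 180.0)
    b.atom("C4", "C", c4)
    b.bond("C3", "C4")
    _phenyl(b, "C4", c2, c3)
    return slots  # remaining slot directions at C2


def _make_clt():
    b = _Builder("CLT", "toy 2-hydroxy-4-phenylbutanoic acid")
    _clt_core(b, with_hydroxyl=True)
    return b.build(stereocenters=("C2",))


def _make_lpr():
    """Lisinopril connection table: carboxyphenylbutyl + lysyl + proline."""
    b = _Builder("LPR", "toy lisinopril")
    slots = _clt_core(b, with_hydroxyl=False)
    # secondary amine bridging to the lysine alpha carbon
    nl = b.pos["C2"] + L_CN * slots[1]
    b.atom("NL", "N", nl)
    b.bond("C2", "NL")
    cal = place_atom(b.pos["C1"], b.pos["C2"], nl, L_CN, TET, 60.0)
    b.atom("CAL", "C", cal)
    b.bond("NL", "CAL")
    # lysine carbonyl toward proline
    cl = place_atom(b.pos["C2"], nl, cal, L_CC, TET, 180.0)
    b.atom("CL", "C", cl)
    b.bond("CAL", "CL")
    ol = place_atom(nl, cal, cl, L_CdO, 120.0, 0.0)
    b.atom("OL", "O", ol)
    b.bond("CL", "OL", "double")
    npp = place_atom(nl, cal, cl, L_CN, 120.0, 180.0)
    b.atom("NP", "N", npp)
    b.bond("CL", "NP")
    # lysine side chain
    side_slots = sp3_slots(cal, [nl, cl])
    cbl = cal + L_CC * side_slots[0]
    b.atom("CBL", "C", cbl)
    b.bond("CAL", "CBL")
    prev2, prev1, cur, last = nl, cal, cbl, "CBL"
    for name, el, length in (("CGL", "C", L_CC), ("CDL", "C", L_CC),
                             ("CEL", "C", L_CC), ("NZL", "N", L_CN)):
        nxt = place_atom(prev2, prev1, cur, length, TET, 180.0)
        b.atom(name, el, nxt)
        b.bond(last, name)
        prev2, prev1, cur, last = prev1, cur, nxt, name
    # proline ring: planar pentagon with its para-ish axis continuing CL->NP
    radial = _unit(npp - cl)
    normal = _unit(np.cross(radial, cal - cl))
    verts = _regular_ring(npp, radial, normal, 5, 1.50)
    for name, v in zip(("CAP", "CBP", "CGP", "CDP"), verts[1:]):
        b.atom(name, "C", v)
    for a, c in (("NP", "CAP"), ("CAP", "CBP"), ("CBP", "CGP"),
                 ("CGP", "CDP"), ("CDP", "NP")):
        b.bond(a, c)
    cap = b.pos["CAP"]
    # proline free carboxyl, out of the ring plane
    pslots = sp3_slots(cap, [npp, b.pos["CBP"]])
    cp = cap + L_CC * pslots[0]
    b.atom("CP", "C", cp)
    b.bond("CAP", "CP")
    op = place_atom(npp, cap, cp, L_CdO, 120.0, 0.0)
    oxp = place_atom(npp, cap, cp, L_CO, 120.0, 180.0)
    b.atom("OP", "O", op)
    b.atom("OXP", "O", oxp)
    b.bond("CP", "OP", "double")
    b.bond("CP", "OXP")
    return b.build(stereocenters=("C2", "CAL", "CAP"))


def _make_ggg():
    """Triglycine as a single hetero ligand (extended backbone)."""
    b = _Builder("GGG", "toy glycylglycylglycine")
    n1 = np.zeros(3)
    ca1 = np.array([L_CN, 0.0, 0.0])
    c1 = place_atom(np.array([0.0, 1.0, 0.0]), n1, ca1, L_CC, TET, 150.0)
    b.atom("N1", "N", n1)
    b.atom("CA1", "C", ca1)
    b.atom("C1", "C", c1)
    b.bond("N1", "CA1")
    b.bond("CA1", "C1")
    prev2, prev1, cur = n1, ca1, c1
    for i in (1, 2):
        o = place_atom(prev2, prev1, cur, L_CdO, 120.0, 0.0)
        b.atom(f"O{i}", "O", o)
        b.bond(f"C{i}", f"O{i}", "double")
        n = place_atom(prev2, prev1, cur, L_CN, 120.0, 180.0)
        b.atom(f"N{i + 1}", "N", n)
        b.bond(f"C{i}", f"N{i + 1}")
        ca = place_atom(prev1, cur, n, L_CN, 120.0, 180.0)
        b.atom(f"CA{i + 1}", "C", ca)
        b.bond(f"N{i + 1}", f"CA{i + 1}")
        c = place_atom(cur, n, ca, L_CC, TET, 180.0)
        b.atom(f"C{i + 1}", "C", c)
        b.bond(f"CA{i + 1}", f"C{i + 1}")
        prev2, prev1, cur = n, ca, c
    o3 = place_atom(prev2, prev1, cur, L_CdO, 120.0, 0.0)
    oxt = place_atom(prev2, prev1, cur, L_CO, 120.0, 180.0)
    b.atom("O3", "O", o3)
    b.atom("OXT", "O", oxt)
    b.bond("C3", "O3", "double")
    b.bond("C3", "OXT")
    b.leaving.add("OXT")
    return b.build()


def make_toy_dictionary() -> Dictionary:
    """Deterministic toy component dictionary (15 definitions)."""
    makers = [_make_gly, _make_ala, _make_pro, _make_lys,
              _make_man, _make_nag, _make_ndg, _make_mes,
              _make_bnz, _make_pyr, _make_chx, _make_zn,
              _make_clt, _make_lpr, _make_ggg]
    return Dictionary([mk() for mk in makers])


# ---------------------------------------------------------------------------
# entry assembly

PERTURBATIONS = ("none", "flatten_chiral", "invert_parity",
                 "change_bond_order", "rename_atoms", "relabel_id",
                 "delete_atom", "link_to_polymer")


def _heavy_neighbor_positions(comp: ComponentDefinition, atom: str,
                              pos: dict[str, np.ndarray]):
    out = []
    for bd in comp.bonds:
        other = None
        if bd.atom1 == atom:
            other = bd.atom2
        elif bd.atom2 == atom:
            other = bd.atom1
        if other and other in pos and \
                comp.atom(other).element.upper() != "H":
            out.append((other, pos[other]))
    return out


def _plane_of_neighbors(comp, atom, pos):
    nbrs = _heavy_neighbor_positions(comp, atom, pos)
    if len(nbrs) < 3:
        raise ValueError(f"{atom} has fewer than 3 heavy neighbors")
    pts = np.array([p for _, p in nbrs[:3]])
    centroid = pts.mean(axis=0)
    normal = _unit(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
    return centroid, normal


def _apply_perturbation(comp: ComponentDefinition, names, elements, coords,
                        perturbation):
    """Mutates the copied atom arrays; returns (names, elements, coords,
    comp_id_override, polymer_request)."""
    pos = {n: coords[i] for i, n in enumerate(names)}
    kind, *args = perturbation
    if kind == "none":
        return names, elements, coords, None, None
    if kind == "flatten_chiral":
        atom, = args
        centroid, normal = _plane_of_neighbors(comp, atom, pos)
        i = names.index(atom)
        p = coords[i]
        coords[i] = p - normal * float(np.dot(p - centroid, normal))
        return names, elements, coords, None, None
    if kind == "invert_parity":
        # swap a terminal substituent into the implicit-H slot: reflect it
        # through the plane of the center and its other two neighbors (the
        # anomer flip); with no terminal substituent reflect the center
        # through its neighbor plane instead
        atom, = args
        nbrs = _heavy_neighbor_positions(comp, atom, pos)
        terminal = [nm for nm, _ in nbrs
                    if len(_heavy_neighbor_positions(comp, nm, pos)) == 1]
        if terminal:
            t = terminal[0]
            others = [p for nm, p in nbrs if nm != t][:2]
            a = pos[atom]
            normal = _unit(np.cross(others[0] - a, others[1] - a))
            i = names.index(t)
            p = coords[i]
            coords[i] = p - 2.0 * normal * float(np.dot(p - a, normal))
        else:
            centroid, normal = _plane_of_neighbors(comp, atom, pos)
            i = names.index(atom)
            p = coords[i]
            coords[i] = p - 2.0 * normal * float(np.dot(p - centroid, normal))
        return names, elements, coords, None, None
    if kind == "change_bond_order":
        a1, a2 = args
        bond = next((bd for bd in comp.bonds
                     if {bd.atom1, bd.atom2} == {a1, a2}), None)
        if bond is None:
            raise ValueError(f"{comp.comp_id}: no bond {a1}-{a2}")
        from ._chem import reference_lengths
        refs = reference_lengths(comp.atom(a1).element, comp.atom(a2).element)
        target_order = "single" if bond.order != "single" else "double"
        if target_order not in refs:
            raise ValueError(f"no reference length to retarget {a1}-{a2}")
        # translate the a2-side component along the bond axis
        import networkx as nx
        g = nx.Graph()
        for bd in comp.bonds:
            g.add_edge(bd.atom1, bd.atom2)
        g.remove_edge(a1, a2)
        side = nx.node_connected_component(g, a2) if a2 in g else {a2}
        axis = _unit(pos[a2] - pos[a1])
        shift = (refs[target_order]
                 - float(np.linalg.norm(pos[a2] - pos[a1]))) * axis
        for i, n in enumerate(names):
            if n in side:
                coords[i] = coords[i] + shift
        return names, elements, coords, None, None
    if kind == "rename_atoms":
        new_names = [f"X{i + 1}" for i in range(len(names))]
        return new_names, elements, coords, None, None
    if kind == "relabel_id":
        new_id, = args
        return names, elements, coords, new_id, None
    if kind == "delete_atom":
        atom, = args
        if atom not in names:
            raise ValueError(f"{comp.comp_id}: no atom {atom}")
        i = names.index(atom)
        return (names[:i] + names[i + 1:], elements[:i] + elements[i + 1:],
                coords[:i] + coords[i + 1:], None, None)
    if kind == "link_to_polymer":
        atom, = args
        # the flagged leaving substituent on the attachment atom departs and
        # an asparagine-like side-chain nitrogen takes its position
        leaving = None
        for bd in comp.bonds:
            other = bd.atom2 if bd.atom1 == atom else \
                bd.atom1 if bd.atom2 == atom else None
            if other and comp.atom(other).leaving:
                leaving = other
                break
        if leaving is None:
            raise ValueError(
                f"{comp.comp_id}: no leaving atom bonded to {atom}")
        i = names.index(leaving)
        anchor_i = names.index(atom)
        site = (np.asarray(coords[anchor_i]),
                np.asarray(coords[i]))  # attachment atom, departed position
        return (names[:i] + names[i + 1:], elements[:i] + elements[i + 1:],
                coords[:i] + coords[i + 1:], None, site)
    raise ValueError(f"unknown perturbation {kind!r}")


def _asn_residue(chain: str, seqnum: int, attach_pos, nd2_pos) -> Residue:
    """Asparagine-like polymer residue whose side-chain ND2 sits at the
    glycosylation position, the rest growing away from the ligand."""
    direction = _unit(np.asarray(nd2_pos) - np.asarray(attach_pos))
    nd2 = np.asarray(nd2_pos, float)
    cg = nd2 + 1.47 * direction
    od1 = place_atom(attach_pos, nd2, cg, L_CdO, 120.0, 0.0)
    cb = place_atom(attach_pos, nd2, cg, L_CC, 120.0, 180.0)
    ca = place_atom(nd2, cg, cb, L_CC, TET, 180.0)
    n = place_atom(cg, cb, ca, L_CN, TET, 180.0)
    c = place_atom(cb, ca, n, L_CC, TET, 60.0)
    o = place_atom(ca, n, c, L_CdO, 120.0, 0.0)
    names = ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"]
    els = ["N", "C", "C", "O", "C", "C", "O", "N"]
    xyzs = [n, ca, c, o, cb, cg, od1, nd2]
    return Residue(chain=chain, seqnum=seqnum, comp_id="ASN", polymer=True,
                   atoms=[EntryAtom(name=nm, element=el,
                                    xyz=tuple(np.round(p, 3)))
                          for nm, el, p in zip(names, els, xyzs)])


def make_entry(spec, seed: int = 0, dictionary: Dictionary | None = None,
               entry_id: str = "TOY1", jitter: float = 0.02,
               ) -> StructureEntry:
    """Assemble a synthetic entry from perturbable copies of toy components.

    ``spec`` is a list of (comp_id, count, perturbation) with perturbation
    either None / "none" or a tuple (kind, *args) from
    :data:`PERTURBATIONS`. Instances are placed on a 25 A grid; coordinates
    get seeded uniform jitter (default 0.02 A, small enough that perception
    stays unambiguous). Perturbations touch coordinates and labels only —
    never the dictionary.
    """
    d = dictionary or make_toy_dictionary()
    rng = np.random.default_rng(seed)
    entry = StructureEntry(entry_id=entry_id)
    slot = 0
    het_seq = 1001
    asn_seq = 219
    for comp_id, count, perturbation in spec:
        if comp_id not in d:
            raise ValueError(f"unknown comp_id {comp_id!r}")
        comp = d[comp_id]
        if perturbation in (None, "none"):
            perturbation = ("none",)
        perts = ([tuple(perturbation)] if isinstance(perturbation[0], str)
                 else [tuple(p) for p in perturbation])
        for _ in range(count):
            names = [a.name for a in comp.heavy_atoms()]
            elements = [a.element for a in comp.heavy_atoms()]
            coords = [np.asarray(a.xyz, float)
                      + rng.uniform(-jitter, jitter, 3)
                      for a in comp.heavy_atoms()]
            new_id = site = None
            for pert in perts:
                names, elements, coords, nid, ste = _apply_perturbation(
                    comp, names, elements, coords, pert)
                new_id = nid or new_id
                site = ste or site
            offset = np.array([25.0 * (slot % 8), 25.0 * (slot // 8), 0.0])
            res = Residue(chain="C", seqnum=het_seq, comp_id=new_id or comp_id,
                          polymer=False,
                          atoms=[EntryAtom(name=nm, element=el,
                                           xyz=tuple(np.round(p + offset, 3)))
                                 for nm, el, p in zip(names, elements,
                                                      coords)])
            entry.residues.append(res)
            if site is not None:
                attach, departed = site
                entry.residues.append(_asn_residue(
                    "A", asn_seq, attach + offset, departed + offset))
                asn_seq += 1
            het_seq += 1
            slot += 1
    entry.validate()
    return entry
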