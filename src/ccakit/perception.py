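"""Chemical-graph perception from 3D coordinates and from stored definitions.

An instance observed in a structure entry carries only elements and
coordinates, so its bonds, bond orders, hybridization, chirality parity and
aromaticity must be derived geometrically. A dictionary definition instead
stores bonds, orders and stereo flags, and its derived attributes are taken
from those records (with its idealized coordinates supplying the geometric
parity). Both routes populate the same :class:`MolecularGraph` attributes so
that instance and definition can be compared category by category.

Perception rules (all thresholds overridable through a config mapping):

* bonds: atoms *i*, *j* are bonded iff ``d(i,j) <= r_cov(i) + r_cov(j) +
  tolerance``; contacts between a metal and N/O/S within 3.0 A are recorded
  as coordination contacts and never become covalent edges, so metal sites do
  not fuse their ligands into one molecule;
* bond order: nearest reference length for the element pair;
* hybridization: a center with three neighbors is sp2 when its bond-angle
  sum reaches the planarity threshold (default 355 deg), else sp3; four
  neighbors give sp3; two neighbors near 180 deg give sp;
* handedness: the parity (+1/-1) of an sp3 center with at least three heavy
  neighbors of pairwise-distinct canonical ranks is the sign of the
  determinant of the vectors to its three highest-ranked neighbors taken in
  rank order — a convention-free quantity that flips under reflection;
* aromaticity: smallest-set-of-smallest-rings, then a per-ring Hückel count.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Mapping, Sequence

import networkx as nx
import numpy as np

from . import _chem
from .ccdio import ComponentDefinition

__all__ = [
    "MolecularGraph", "perceive_bonds", "perceive_hybridization",
    "assign_handedness", "perceive_aromaticity", "canonical_ranks",
    "graph_from_definition", "perceive_all", "DEFAULT_CONFIG",
]

DEFAULT_CONFIG: dict[str, float] = {
    "bond_tolerance": _chem.BOND_TOLERANCE,
    "metal_contact_cutoff": _chem.METAL_CONTACT_CUTOFF,
    "sp2_angle_sum": 355.0,      # degrees
    "sp_angle": 170.0,           # degrees; >= this with 2 neighbors -> sp
    "ring_planarity": 0.15,      # A, max deviation from best-fit ring plane
}


class MolecularGraph:
    """Thin wrapper over an undirected networkx graph keyed by atom name.

    Node attributes: ``element``, ``xyz`` (optional), ``hyb``, ``chiral``,
    ``parity`` (+1/-1/0), ``aromatic``, ``rank``. Edge attributes: ``order``
    (single/double/triple/unspecified) and ``aromatic``. Coordination
    contacts (metal sites) are kept off-graph in ``coordination``.
    """

    def __init__(self) -> None:
        self.g = nx.Graph()
        self.coordination: list[tuple[str, str, float]] = []

    # -- construction -----------------------------------------------------
    def add_atom(self, name: str, element: str, xyz=None, charge: int = 0,
                 is_cap: bool = False) -> None:
        self.g.add_node(name, element=element.capitalize(),
                        xyz=None if xyz is None else np.asarray(xyz, float),
                        charge=charge, cap=is_cap,
                        hyb="other", chiral=False, parity=0,
                        aromatic=False, rank=0)

    def add_bond(self, a: str, b: str, order: str = "unspecified",
                 aromatic: bool = False) -> None:
        if a == b:
            raise ValueError(f"self-bond on {a}")
        self.g.add_edge(a, b, order=order, aromatic=aromatic)

    # -- views ------------------------------------------------------------
    def atoms(self) -> list[str]:
        return list(self.g.nodes)

    def element(self, name: str) -> str:
        return self.g.nodes[name]["element"]

    def xyz(self, name: str) -> np.ndarray:
        return self.g.nodes[name]["xyz"]

    def is_heavy(self, name: str) -> bool:
        return self.element(name).upper() != "H"

    def heavy_atoms(self) -> list[str]:
        return [n for n in self.g.nodes if self.is_heavy(n)]

    def heavy_neighbors(self, name: str) -> list[str]:
        return [n for n in self.g.neighbors(name) if self.is_heavy(n)]

    def heavy_subgraph(self) -> "MolecularGraph":
        sub = MolecularGraph()
        sub.g = self.g.subgraph(self.heavy_atoms()).copy()
        sub.coordination = list(self.coordination)
        return sub

    def element_counts(self) -> tuple[tuple[str, int], ...]:
        counts: dict[str, int] = {}
        for n in self.heavy_atoms():
            counts[self.element(n)] = counts.get(self.element(n), 0) + 1
        return tuple(sorted(counts.items()))

    def bond_label(self, a: str, b: str) -> str:
        """Comparison label for a bond: 'aromatic' trumps the numeric order."""
        data = self.g.edges[a, b]
        return "aromatic" if data.get("aromatic") else data.get(
            "order", "unspecified")

    def incident_order_multiset(self, name: str) -> tuple[str, ...]:
        labels = [self.bond_label(name, nb)
                  for nb in self.heavy_neighbors(name)]
        return tuple(sorted(labels))

    def copy(self) -> "MolecularGraph":
        new = MolecularGraph()
        new.g = self.g.copy()
        new.coordination = list(self.coordination)
        return new


def _config(config: Mapping | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    return cfg


# ---------------------------------------------------------------------------
# bonds

def perceive_bonds(atoms: Sequence[tuple], config: Mapping | None = None,
                   ) -> MolecularGraph:
    """Build the covalent graph from (name, element, xyz) triples.

    Accepts either (element, xyz) pairs (names auto-generated) or
    (name, element, xyz) triples. Bond orders are classified by nearest
    reference length.
    """
    cfg = _config(config)
    mg = MolecularGraph()
    entries = []
    for i, a in enumerate(atoms):
        if len(a) == 2:
            element, xyz = a
            name = f"{element.upper()}{i + 1}"
        else:
            name, element, xyz = a[0], a[1], a[2]
        entries.append((name, element, np.asarray(xyz, float)))
    if not entries:
        raise ValueError("no atoms")
    for name, element, xyz in entries:
        _chem.covalent_radius(element)  # raises for unknown elements
        mg.add_atom(name, element, xyz)
    names = [e[0] for e in entries]
    coords = np.array([e[2] for e in entries])
    if len(entries) > 1:
        from scipy.spatial import cKDTree
        tree = cKDTree(coords)
        max_r = max(_chem.covalent_radius(e[1]) for e in entries)
        cutoff = max(2 * max_r + cfg["bond_tolerance"],
                     cfg["metal_contact_cutoff"])
        for i, j in sorted(tree.query_pairs(cutoff)):
            ni, nj = names[i], names[j]
            ei, ej = mg.element(ni), mg.element(nj)
            d = float(np.linalg.norm(coords[i] - coords[j]))
            metal_pair = _chem.is_metal(ei) or _chem.is_metal(ej)
            if metal_pair:
                other = ej if _chem.is_metal(ei) else ei
                if other.upper() in ("N", "O", "S") and \
                        d <= cfg["metal_contact_cutoff"]:
                    mg.coordination.append((ni, nj, d))
                continue
            rsum = (_chem.covalent_radius(ei) + _chem.covalent_radius(ej)
                    + cfg["bond_tolerance"])
            if d <= rsum:
                mg.add_bond(ni, nj, order=_chem.classify_order(ei, ej, d))
    return mg


# ---------------------------------------------------------------------------
# hybridization

def _angle(a: np.ndarray, center: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - center, b - center
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def perceive_hybridization(mg: MolecularGraph,
                           config: Mapping | None = None) -> MolecularGraph:
    """Assign sp/sp2/sp3/other per atom from bond-angle geometry."""
    cfg = _config(config)
    for n in mg.g.nodes:
        nbrs = list(mg.g.neighbors(n))
        xyz = mg.g.nodes[n]["xyz"]
        if xyz is None or len(nbrs) < 2:
            mg.g.nodes[n]["hyb"] = "other"
            continue
        if len(nbrs) >= 4:
            mg.g.nodes[n]["hyb"] = "sp3"
        elif len(nbrs) == 3:
            total = sum(
                _angle(mg.xyz(a), xyz, mg.xyz(b))
                for a, b in itertools.combinations(nbrs, 2))
            mg.g.nodes[n]["hyb"] = (
                "sp2" if total >= cfg["sp2_angle_sum"] else "sp3")
        else:  # 2 neighbors
            ang = _angle(mg.xyz(nbrs[0]), xyz, mg.xyz(nbrs[1]))
            mg.g.nodes[n]["hyb"] = "sp" if ang >= cfg["sp_angle"] else "sp3"
    return mg


# ---------------------------------------------------------------------------
# canonical ranks (Morgan-style iterative refinement)

def canonical_ranks(mg: MolecularGraph) -> MolecularGraph:
    """Permutation-invariant total preorder on heavy atoms.

    Seeded by (element, heavy degree) and refined with sorted neighbor
    labels to a fixed point. Equal inputs under relabeling yield equal rank
    multisets; symmetric atoms keep equal ranks (ties are resolved only by
    declaring would-be stereocenters non-chiral).
    """
    heavy = mg.heavy_atoms()
    labels = {n: (mg.element(n), len(mg.heavy_neighbors(n))) for n in heavy}
    nclasses = 0
    for _ in range(len(heavy) + 1):
        signature = {
            n: (labels[n],
                tuple(sorted(labels[m] for m in mg.heavy_neighbors(n))))
            for n in heavy}
        distinct = sorted(set(signature.values()))
        new = {n: distinct.index(signature[n]) for n in heavy}
        if len(distinct) == nclasses:
            break
        nclasses = len(distinct)
        labels = new
    for n in mg.g.nodes:
        mg.g.nodes[n]["rank"] = labels.get(n, -1) if mg.is_heavy(n) else -1
    return mg


# ---------------------------------------------------------------------------
# handedness

def _parity_from_coords(mg: MolecularGraph, center: str) -> int:
    """Sign of det of vectors to the three highest-ranked heavy neighbors
    taken in decreasing rank order (name-ordered among equals never occurs:
    equal ranks disqualify the center)."""
    nbrs = mg.heavy_neighbors(center)
    ranked = sorted(nbrs, key=lambda n: -mg.g.nodes[n]["rank"])[:3]
    c = mg.xyz(center)
    mat = np.stack([mg.xyz(n) - c for n in ranked])
    det = float(np.linalg.det(mat))
    return 1 if det > 0 else -1 if det < 0 else 0


def assign_handedness(mg: MolecularGraph,
                      config: Mapping | None = None) -> MolecularGraph:
    """Flag chiral centers and assign their geometric parity.

    A center qualifies iff it is sp3, has >= 3 heavy neighbors, and those
    neighbors carry pairwise-distinct canonical ranks (pro-chiral centers
    with equivalent branches are excluded).
    """
    canonical_ranks(mg)
    for n in mg.g.nodes:
        node = mg.g.nodes[n]
        node["chiral"], node["parity"] = False, 0
        if not mg.is_heavy(n) or node["hyb"] != "sp3":
            continue
        nbrs = mg.heavy_neighbors(n)
        if len(nbrs) < 3 or node["xyz"] is None:
            continue
        ranks = [mg.g.nodes[m]["rank"] for m in nbrs]
        if len(set(ranks)) != len(ranks):
            continue
        parity = _parity_from_coords(mg, n)
        if parity:
            node["chiral"], node["parity"] = True, parity
    return mg


# ---------------------------------------------------------------------------
# aromaticity

def _sssr(mg: MolecularGraph) -> list[list[str]]:
    heavy = mg.g.subgraph(mg.heavy_atoms())
    return [list(c) for c in nx.minimum_cycle_basis(heavy)]


def _ring_planar(mg: MolecularGraph, ring: list[str], tol: float) -> bool:
    coords = np.array([mg.xyz(n) for n in ring])
    centered = coords - coords.mean(axis=0)
    # smallest singular direction = best-fit plane normal
    _, s, vh = np.linalg.svd(centered)
    dev = np.abs(centered @ vh[2])
    return bool(dev.max() <= tol)


def _pi_electrons_geometric(mg: MolecularGraph, ring: list[str]) -> int | None:
    """Hückel contributions for a coordinate-perceived ring (no orders):
    C -> 1 (requires sp2 when 3-coordinate); 2-coordinate N -> 1 (pyridine
    type); 3-coordinate N and O/S -> 2 lone-pair electrons."""
    total = 0
    for n in ring:
        el = mg.element(n).upper()
        degree = len(mg.heavy_neighbors(n))
        hyb = mg.g.nodes[n]["hyb"]
        if el == "C":
            if degree >= 3 and hyb != "sp2":
                return None
            total += 1
        elif el == "N":
            total += 1 if degree == 2 else 2
        elif el in ("O", "S"):
            total += 2
        else:
            return None
    return total


def _pi_electrons_orders(mg: MolecularGraph, ring: list[str]) -> int | None:
    """Hückel contributions from stored bond orders: ring atom in a ring
    double bond -> 1; ring N/O/S without one -> 2; ring C with an exocyclic
    double bond -> 0; a saturated ring C fails the ring."""
    ring_set = set(ring)
    total = 0
    for n in ring:
        el = mg.element(n).upper()
        orders_in = [mg.g.edges[n, m].get("order") for m in
                     mg.heavy_neighbors(n) if m in ring_set]
        orders_out = [mg.g.edges[n, m].get("order") for m in
                      mg.heavy_neighbors(n) if m not in ring_set]
        if "double" in orders_in or "triple" in orders_in:
            total += 1
        elif el in ("N", "O", "S"):
            total += 2
        elif el == "C":
            if "double" in orders_out:
                total += 0
            else:
                return None  # sp3 ring carbon
        else:
            return None
    return total


def perceive_aromaticity(mg: MolecularGraph, from_orders: bool = False,
                         config: Mapping | None = None) -> MolecularGraph:
    """Flag aromatic atoms and ring bonds per smallest ring passing Hückel.

    ``from_orders`` selects the stored-bond-order contribution table (for
    definition graphs); otherwise ring planarity plus geometric proxies are
    used (for coordinate-perceived instances).
    """
    cfg = _config(config)
    for n in mg.g.nodes:
        mg.g.nodes[n].setdefault("aromatic", False)
    for ring in _sssr(mg):
        if len(ring) < 3:
            continue
        # order ring atoms along the cycle
        sub = mg.g.subgraph(ring)
        try:
            cycle = [ring[0]]
            while len(cycle) < len(ring):
                nxt = [m for m in sub.neighbors(cycle[-1]) if m not in cycle]
                if not nxt:
                    break
                cycle.append(sorted(nxt)[0])
            ring = cycle
        except nx.NetworkXError:
            pass
        if from_orders:
            pi = _pi_electrons_orders(mg, ring)
        else:
            if any(mg.g.nodes[n]["xyz"] is None for n in ring) or \
                    not _ring_planar(mg, ring, cfg["ring_planarity"]):
                continue
            pi = _pi_electrons_geometric(mg, ring)
        if pi is None or pi < 2 or (pi - 2) % 4 != 0:
            continue
        for n in ring:
            mg.g.nodes[n]["aromatic"] = True
        for a, b in zip(ring, ring[1:] + ring[:1]):
            if mg.g.has_edge(a, b):
                mg.g.edges[a, b]["aromatic"] = True
    return mg


# ---------------------------------------------------------------------------
# definitions and the full pipeline

def graph_from_definition(comp: ComponentDefinition,
                          config: Mapping | None = None) -> MolecularGraph:
    """Build the perceived graph of a definition from its stored records.

    Bonds and orders come from the definition; chirality from its stereo
    flags with geometric parity from the idealized coordinates; aromaticity
    from stored flags when any are set, else perceived from the orders.
    """
    comp.validate()
    mg = MolecularGraph()
    for a in comp.atoms:
        mg.add_atom(a.name, a.element, a.xyz, charge=a.charge)
    for b in comp.bonds:
        mg.add_bond(b.atom1, b.atom2, order=b.order, aromatic=b.aromatic)
    canonical_ranks(mg)
    # hybridization from orders: any double -> sp2, any triple -> sp
    for n in mg.g.nodes:
        orders = [mg.g.edges[n, m].get("order")
                  for m in mg.g.neighbors(n)]
        aromatic_flags = [mg.g.edges[n, m].get("aromatic")
                          for m in mg.g.neighbors(n)]
        if "triple" in orders:
            mg.g.nodes[n]["hyb"] = "sp"
        elif "double" in orders or any(aromatic_flags):
            mg.g.nodes[n]["hyb"] = "sp2"
        else:
            mg.g.nodes[n]["hyb"] = "sp3" if orders else "other"
    if any(a.aromatic for a in comp.atoms) or \
            any(b.aromatic for b in comp.bonds):
        for a in comp.atoms:
            mg.g.nodes[a.name]["aromatic"] = a.aromatic
    else:
        perceive_aromaticity(mg, from_orders=True, config=config)
    for a in comp.atoms:
        if a.stereo in ("R", "S"):
            if len(mg.heavy_neighbors(a.name)) < 3:
                raise ValueError(
                    f"{comp.comp_id}: stereo flag on {a.name} with fewer "
                    f"than 3 heavy neighbors")
            mg.g.nodes[a.name]["chiral"] = True
            mg.g.nodes[a.name]["parity"] = _parity_from_coords(mg, a.name)
    return mg


def perceive_all(atoms: Sequence[tuple],
                 config: Mapping | None = None) -> MolecularGraph:
    """Full geometric perception pipeline for an observed instance."""
    mg = perceive_bonds(atoms, config)
    perceive_hybridization(mg, config)
    perceive_aromaticity(mg, from_orders=False, config=config)
    assign_handedness(mg, config)
    return mg
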