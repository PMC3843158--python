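"""Decomposition of peptide-like ligands into dictionary-matchable pieces.

A large peptidomimetic (an inhibitor or antibiotic assembled from amino-acid
like units) is cut at its backbone-forming bonds, each fragment is completed
back to its free and neutral charge state — the carbon side of every cut
receives the -OH it lost on condensation, the nitrogen side an -H — and the
capped fragments are searched against the component dictionary. Fragments
are then ordered from the N-terminus to the C-terminus (reversal and cyclic
rotation are available for cyclic peptides) and the decomposition can be
written back to the entry either as a true polymer or as a single ligand
with subcomponent sequence information.

Cut-point selection is a heuristic the annotator may override: it selects
acyclic C-N bonds that are amides (the carbon carries a double-bonded
oxygen), plus secondary-amine backbone bonds of the lisinopril type — the
nitrogen is not an amide nitrogen, has two carbon substituents, and the
bond's carbon is attached to a carboxyl carbon. Amide bonds to ring
nitrogens (proline) are cleavable because the bond itself, not the nitrogen,
must be acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ccdio import Dictionary, EntryAtom, Residue, StructureEntry
from .matching import ComponentInstance, MatchResult, match_instance
from .perception import MolecularGraph, perceive_all

__all__ = ["Fragment", "Decomposition", "select_cleavage_bonds", "chop",
           "order_sequence", "apply_chop_to_entry"]

CAP_C_O = 1.43
CAP_N_H = 1.01


@dataclass
class Fragment:
    members: list[str]            # parent atom names
    cap_atoms: list[str]          # names of appended cap atoms
    graph: MolecularGraph | None = None
    match: MatchResult | None = None

    @property
    def top_id(self) -> str | None:
        return self.match.top_hit.comp_id if self.match and \
            self.match.top_hit else None

    def is_matched(self) -> bool:
        return (self.match is not None and self.match.top_hit is not None
                and self.match.top_hit.score.is_exact())


@dataclass
class Decomposition:
    parent: MolecularGraph
    cleaved_bonds: list[tuple[str, str]]   # (carbon side, nitrogen side)
    fragments: list[Fragment] = field(default_factory=list)
    mode: str = "linear"

    def fragment_of(self, atom: str) -> int:
        for i, f in enumerate(self.fragments):
            if atom in f.members:
                return i
        raise KeyError(atom)


# ---------------------------------------------------------------------------

def _ring_edges(g: MolecularGraph) -> set[frozenset]:
    heavy = g.g.subgraph(g.heavy_atoms())
    edges: set[frozenset] = set()
    for cycle in nx.cycle_basis(heavy):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            edges.add(frozenset((a, b)))
    return edges


def _has_double_oxygen(g: MolecularGraph, carbon: str) -> bool:
    return any(g.element(nb).upper() == "O"
               and g.bond_label(carbon, nb) == "double"
               for nb in g.heavy_neighbors(carbon))


def _is_carboxyl_carbon(g: MolecularGraph, carbon: str) -> bool:
    if g.element(carbon).upper() != "C":
        return False
    labels = [(g.element(nb).upper(), g.bond_label(carbon, nb))
              for nb in g.heavy_neighbors(carbon)]
    return ("O", "double") in labels and ("O", "single") in labels


def select_cleavage_bonds(g: MolecularGraph) -> list[tuple[str, str]]:
    """Automatic cut points, returned as (carbon, nitrogen) pairs.

    The user may add or remove bonds before chopping; a single free amino
    acid selects nothing.
    """
    rings = _ring_edges(g)
    out: list[tuple[str, str]] = []
    for a, b in g.g.edges:
        if not (g.is_heavy(a) and g.is_heavy(b)):
            continue
        els = {g.element(a).upper(), g.element(b).upper()}
        if els != {"C", "N"}:
            continue
        if frozenset((a, b)) in rings:
            continue
        c, n = (a, b) if g.element(a).upper() == "C" else (b, a)
        if _has_double_oxygen(g, c):
            out.append((c, n))
            continue
        # secondary-amine backbone bond: N not in an amide, two carbon
        # substituents, and the bond's carbon attached to a carboxyl carbon
        carbon_nbrs = [m for m in g.heavy_neighbors(n)
                       if g.element(m).upper() == "C"]
        if len(carbon_nbrs) < 2:
            continue
        if any(_has_double_oxygen(g, m) for m in carbon_nbrs):
            continue  # amide nitrogen; the amide rule owns this residue edge
        if any(_is_carboxyl_carbon(g, m) for m in g.heavy_neighbors(c)
               if m != n):
            out.append((c, n))
    return sorted(out)


def chop(g: MolecularGraph, bonds: list[tuple[str, str]],
         d: Dictionary, config=None) -> Decomposition:
    """Cut the listed bonds, cap both sides, match every fragment.

    Each bond must be an existing C-N edge. Cutting a ring bond is only
    legal when, together with the other cuts, it opens the backbone into
    separate fragments; a cut whose two ends stay in one fragment is an
    error naming the bond.
    """
    norm_bonds: list[tuple[str, str]] = []
    for a, b in bonds:
        if not g.g.has_edge(a, b):
            raise ValueError(f"no bond {a}-{b} in parent graph")
        c, n = (a, b) if g.element(a).upper() == "C" else (b, a)
        norm_bonds.append((c, n))
    work = g.g.subgraph(g.heavy_atoms()).copy()
    work.remove_edges_from(norm_bonds)
    comp_of: dict[str, int] = {}
    components = sorted(nx.connected_components(work), key=min)
    for i, comp in enumerate(components):
        for atom in comp:
            comp_of[atom] = i
    for c, n in norm_bonds:
        if comp_of[c] == comp_of[n]:
            raise ValueError(
                f"cleaving {c}-{n} does not separate the backbone "
                "(ring bond without a second opening cut)")
    dec = Decomposition(parent=g, cleaved_bonds=list(norm_bonds))
    frag_atoms: list[list[tuple]] = []
    frag_caps: list[list[str]] = []
    for comp in components:
        members = sorted(comp)
        atoms = [(nm, g.element(nm), tuple(g.xyz(nm))) for nm in members]
        frag_atoms.append(atoms)
        frag_caps.append([])
    for idx, (c, n) in enumerate(norm_bonds, start=1):
        vc, vn = np.asarray(g.xyz(c)), np.asarray(g.xyz(n))
        axis = (vn - vc) / np.linalg.norm(vn - vc)
        # -OH onto the carbon side, -H onto the nitrogen side
        ci, ni = comp_of[c], comp_of[n]
        o_name, h_name = f"OXC{idx}", f"HXN{idx}"
        frag_atoms[ci].append((o_name, "O", tuple(vc + CAP_C_O * axis)))
        frag_caps[ci].append(o_name)
        frag_atoms[ni].append((h_name, "H", tuple(vn - CAP_N_H * axis)))
        frag_caps[ni].append(h_name)
    for comp, atoms, caps in zip(components, frag_atoms, frag_caps):
        frag = Fragment(members=sorted(comp), cap_atoms=caps)
        frag.graph = perceive_all(atoms, config)
        inst = ComponentInstance(chain="", seqnum=0, icode="", comp_id="",
                                 cap_atoms=caps)
        inst.graph = frag.graph
        frag.match = match_instance(inst, d)
        dec.fragments.append(frag)
    return order_sequence(dec, "auto")


# ---------------------------------------------------------------------------

def _fragment_digraph(dec: Decomposition) -> nx.DiGraph:
    dg = nx.DiGraph()
    dg.add_nodes_from(range(len(dec.fragments)))
    for c, n in dec.cleaved_bonds:
        dg.add_edge(dec.fragment_of(c), dec.fragment_of(n))
    return dg


def order_sequence(dec: Decomposition, mode="auto") -> Decomposition:
    """Order fragments N-terminus to C-terminus along the cleaved bonds.

    ``mode``: "auto"/"linear" (follow C->N direction from the unique
    fragment with a free amine), "reverse", or ("rotate", k) for cyclic
    backbones. Branched topologies (a fragment in three or more cleaved
    bonds) require manual ordering and raise.
    """
    dg = _fragment_digraph(dec)
    if any(dg.in_degree(i) + dg.out_degree(i) > 2 for i in dg.nodes):
        raise ValueError("branched decomposition: order fragments manually")
    if mode == "reverse":
        dec.fragments = dec.fragments[::-1]
        dec.mode = "reversed"
        return dec
    if isinstance(mode, tuple) and mode[0] == "rotate":
        k = mode[1] % len(dec.fragments)
        dec.fragments = dec.fragments[k:] + dec.fragments[:k]
        dec.mode = f"cyclic+{k}"
        return dec
    if mode not in ("auto", "linear"):
        raise ValueError(f"unknown ordering mode {mode!r}")
    n = len(dec.fragments)
    if n == 1 or dg.number_of_edges() == 0:
        dec.mode = "linear"
        return dec
    starts = [i for i in dg.nodes if dg.in_degree(i) == 0]
    if not starts:  # cyclic backbone: start at smallest top-hit id
        start = min(dg.nodes,
                    key=lambda i: (dec.fragments[i].top_id or "~",
                                   min(dec.fragments[i].members)))
        dec.mode = "cyclic"
    elif len(starts) == 1:
        start = starts[0]
        dec.mode = "linear"
    else:
        raise ValueError("disconnected decomposition: cannot order")
    order = [start]
    while len(order) < n:
        nxt = [j for j in dg.successors(order[-1]) if j not in order]
        if not nxt:
            break
        order.append(nxt[0])
    if len(order) != n:
        raise ValueError("fragments do not form a single path or cycle")
    dec.fragments = [dec.fragments[i] for i in order]
    return dec


# ---------------------------------------------------------------------------

def apply_chop_to_entry(entry: StructureEntry, residue_key,
                        dec: Decomposition,
                        representation: str = "polymer") -> StructureEntry:
    """Write a decomposition back into the entry.

    polymer: the parent residue is replaced by sequential residues carrying
    the fragments' top-hit component ids and standardized atom names; cap
    atoms are not written. single-ligand: the parent residue stays intact
    and the ordered subcomponent id list is recorded on the entry.
    """
    import copy

    unmatched = [i for i, f in enumerate(dec.fragments) if not f.is_matched()]
    if unmatched:
        raise ValueError(
            f"fragments {unmatched} have no exact dictionary match; create "
            "new definitions before applying the decomposition")
    entry = copy.deepcopy(entry)
    chain, seqnum, icode = residue_key
    parent = entry.residue(chain, seqnum, icode)
    if representation in ("subcomponent", "single-ligand-with-subcomponents"):
        entry.subcomponents[tuple(residue_key)] = [
            f.top_id for f in dec.fragments]
        return entry
    if representation != "polymer":
        raise ValueError(f"unknown representation {representation!r}")
    atom_lookup = {a.name: a for a in parent.atoms}
    new_residues: list[Residue] = []
    for offset, frag in enumerate(dec.fragments):
        mapping = frag.match.top_hit.mapping
        res = Residue(chain=chain, seqnum=seqnum + offset, icode="",
                      comp_id=frag.top_id, polymer=True)
        for name in frag.members:
            src = atom_lookup.get(name)
            if src is None:
                continue
            res.atoms.append(EntryAtom(
                name=mapping.get(name, name), element=src.element,
                xyz=src.xyz, occupancy=src.occupancy, altloc=src.altloc))
        new_residues.append(res)
    idx = entry.residues.index(parent)
    entry.residues[idx:idx + 1] = new_residues
    entry.validate()
    return entry
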