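"""Instance extraction, dictionary search, composite scoring and triage.

Every small-molecule occurrence ("instance") in an entry is searched against
the component dictionary by element-labeled graph isomorphism (prescreened by
the heavy-atom element-count vector), each candidate is scored in the five
composite-score categories — heavy atoms, chiral-center count, handedness,
aromatic atoms, bond order — and the ranked best candidate becomes the Top
Hit with a Match Status of passed / close match / no match.

All comparisons follow the heavy-atom convention: hydrogens never enter
matching or scoring. Category denominators are taken on the definition
(reference) side; a category with an empty eligible set is "n/a".
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism

from ._chem import STANDARD_AMINO_ACIDS, WATERS
from .ccdio import ComponentDefinition, Dictionary, Residue, StructureEntry
from .perception import MolecularGraph, graph_from_definition, perceive_all

__all__ = [
    "CompositeScore", "ComponentInstance", "MatchResult",
    "extract_instances", "find_candidates", "composite_score",
    "score_graphs", "rank_candidates", "assign_status", "match_instance",
    "match_entry", "standardize_nomenclature", "assign_new_id",
    "redundancy_check",
]

NA = "n/a"
_MAX_ISOMORPHISMS = 2000


@dataclass(frozen=True)
class CompositeScore:
    """Five category percentages; a category is n/a when no atom is eligible."""

    heavy_atoms_pct: float | str = NA
    chiral_count_pct: float | str = NA
    handedness_pct: float | str = NA
    aromatic_pct: float | str = NA
    bond_order_pct: float | str = NA

    def categories(self) -> dict[str, float | str]:
        return {
            "heavy_atoms": self.heavy_atoms_pct,
            "chiral_count": self.chiral_count_pct,
            "handedness": self.handedness_pct,
            "aromatic": self.aromatic_pct,
            "bond_order": self.bond_order_pct,
        }

    def defined(self) -> list[float]:
        return [v for v in self.categories().values() if v != NA]

    def mean_defined(self) -> float:
        vals = self.defined()
        return float(np.mean(vals)) if vals else 0.0

    def is_exact(self) -> bool:
        return all(v == 100.0 for v in self.defined())


@dataclass
class Candidate:
    comp_id: str
    score: CompositeScore
    mapping: dict[str, str]       # instance atom name -> definition atom name


@dataclass
class ComponentInstance:
    """One occurrence of a component in an entry: observed heavy atoms with
    coordinates plus the perceived graph and links to its surroundings."""

    chain: str
    seqnum: int
    icode: str
    comp_id: str                  # as deposited
    residue_keys: list[tuple] = field(default_factory=list)
    graph: MolecularGraph | None = None
    group_id: int = 0             # shared by covalently connected instances
    linkages: list = field(default_factory=list)
    cap_atoms: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    def label(self, index: int) -> str:
        return f"{index}_{self.chain}_{self.comp_id}_{self.seqnum}"


@dataclass
class MatchResult:
    instance: ComponentInstance
    candidates: list[Candidate] = field(default_factory=list)
    status: str = "no match"

    @property
    def top_hit(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


# ---------------------------------------------------------------------------
# instance extraction

def _residue_heavy_atoms(res: Residue) -> list[tuple]:
    """(name, element, xyz) triples after the single-conformer rule: for each
    atom name keep the alt-loc with highest occupancy (ties: alphabetically
    first alt-loc id); hydrogens dropped."""
    best: dict[str, tuple] = {}
    for a in res.atoms:
        if a.element.upper() == "H":
            continue
        prev = best.get(a.name)
        if prev is None or (-a.occupancy, a.altloc) < (-prev[0], prev[1]):
            best[a.name] = (a.occupancy, a.altloc, a)
    ordered = [best[a.name][2] for a in res.atoms
               if a.name in best and best[a.name][2] is a]
    return [(a.name, a.element, a.xyz) for a in ordered]


def is_instance_residue(res: Residue, include_waters: bool = False) -> bool:
    if res.comp_id in WATERS and not include_waters:
        return False
    if res.polymer and res.comp_id in STANDARD_AMINO_ACIDS:
        return False
    return True


def extract_instances(entry: StructureEntry, d: Dictionary | None = None,
                      include_waters: bool = False,
                      config=None) -> list[ComponentInstance]:
    """One instance per hetero (or non-standard polymer) residue.

    Hetero residues joined by perceived covalent bonds are not fused: each
    keeps its own instance but covalently connected residues share a
    ``group_id`` and carry the inter-residue linkage records.
    """
    from .environment import detect_linkages  # local import, no cycle at load

    instances: list[ComponentInstance] = []
    for res in sorted(entry.residues, key=lambda r: (r.chain, r.seqnum,
                                                     r.icode)):
        if not is_instance_residue(res, include_waters):
            continue
        atoms = _residue_heavy_atoms(res)
        if not atoms:
            continue
        inst = ComponentInstance(
            chain=res.chain, seqnum=res.seqnum, icode=res.icode,
            comp_id=res.comp_id, residue_keys=[res.key])
        inst.graph = perceive_all(atoms, config)
        instances.append(inst)
    # group covalently connected hetero instances via linkage detection
    by_key = {inst.key: i for i, inst in enumerate(instances)}
    union = nx.Graph()
    union.add_nodes_from(range(len(instances)))
    for i, inst in enumerate(instances):
        links = detect_linkages(inst, entry, config)
        inst.linkages = links
        for link in links:
            pk = (link.partner_chain, link.partner_seqnum, link.partner_icode)
            if link.kind == "covalent" and pk in by_key:
                union.add_edge(i, by_key[pk])
    for gid, comp in enumerate(sorted(nx.connected_components(union),
                                      key=min), start=1):
        for i in comp:
            instances[i].group_id = gid
    return instances


# ---------------------------------------------------------------------------
# candidate generation

def _element_vector_dominates(big, small) -> bool:
    bigd = dict(big)
    return all(bigd.get(el, 0) >= n for el, n in small)


def _node_match(n1: dict, n2: dict) -> bool:
    return n1["element"] == n2["element"]


def _iter_isomorphisms(inst_g: MolecularGraph, def_g: MolecularGraph,
                       subgraph: bool = False):
    """Yield instance-atom -> definition-atom mappings (heavy atoms only)."""
    gi = inst_g.g.subgraph(inst_g.heavy_atoms())
    gd = def_g.g.subgraph(def_g.heavy_atoms())
    if subgraph:
        gm = isomorphism.GraphMatcher(gd, gi, node_match=_node_match)
        for m in itertools.islice(gm.subgraph_isomorphisms_iter(),
                                  _MAX_ISOMORPHISMS):
            yield {v: k for k, v in m.items()}
    else:
        gm = isomorphism.GraphMatcher(gi, gd, node_match=_node_match)
        for m in itertools.islice(gm.isomorphisms_iter(), _MAX_ISOMORPHISMS):
            yield dict(m)


def _best_mapping(inst_g: MolecularGraph, def_g: MolecularGraph,
                  subgraph: bool = False) -> dict[str, str] | None:
    """Score-maximizing isomorphism: maximize (handedness matches, bond-order
    matches), ties broken by the lexicographic sequence of mapped definition
    canonical ranks over instance atoms sorted by (rank, name), then by
    definition atom names — fully deterministic."""
    inst_order = sorted(inst_g.heavy_atoms(),
                        key=lambda n: (inst_g.g.nodes[n]["rank"], n))
    best_key, best = None, None
    for mapping in _iter_isomorphisms(inst_g, def_g, subgraph):
        h = b = 0
        for ia, da in mapping.items():
            ni, nd = inst_g.g.nodes[ia], def_g.g.nodes[da]
            if ni["chiral"] and nd["chiral"] and ni["parity"] == nd["parity"]:
                h += 1
            if inst_g.incident_order_multiset(ia) == \
                    def_g.incident_order_multiset(da):
                b += 1
        tie1 = tuple(def_g.g.nodes[mapping[n]]["rank"] if n in mapping else -1
                     for n in inst_order)
        tie2 = tuple(mapping.get(n, "") for n in inst_order)
        # maximize (h, b); among ties prefer smallest rank sequence, then
        # smallest name sequence
        cmp_key = (h, b)
        if best is None:
            best, best_key = mapping, (cmp_key, tie1, tie2)
        else:
            bc, bt1, bt2 = best_key
            if cmp_key > bc or (cmp_key == bc and (tie1, tie2) < (bt1, bt2)):
                best, best_key = mapping, (cmp_key, tie1, tie2)
    return best


def find_candidates(inst: ComponentInstance, d: Dictionary,
                    k: int = 10) -> list[tuple[str, dict[str, str]]]:
    """Dictionary definitions element-graph-isomorphic to the instance.

    Strict pass: full heavy-atom isomorphism, prescreened by equality of the
    element-count vector. When the strict pass yields nothing (incomplete
    experimental ligands), a fallback subgraph pass maps the instance into
    any definition whose element counts dominate the instance's.
    """
    g = inst.graph
    out: list[tuple[str, dict[str, str]]] = []
    vec = g.element_counts()
    for comp_id in d.by_element_counts(vec):
        def_g = _definition_graph(d, comp_id)
        mapping = _best_mapping(g, def_g, subgraph=False)
        if mapping is not None:
            out.append((comp_id, mapping))
            if len(out) >= k:
                return out
    if out:
        return out
    n_inst = len(g.heavy_atoms())
    for comp_id in d.ids():
        def_g = _definition_graph(d, comp_id)
        if len(def_g.heavy_atoms()) <= n_inst:
            continue
        if not _element_vector_dominates(def_g.element_counts(), vec):
            continue
        mapping = _best_mapping(g, def_g, subgraph=True)
        if mapping is not None:
            out.append((comp_id, mapping))
            if len(out) >= k:
                break
    return out


def _definition_graph(d: Dictionary, comp_id: str) -> MolecularGraph:
    cache = getattr(d, "_graph_cache", None)
    if cache is None:
        return graph_from_definition(d[comp_id])
    if comp_id not in cache:
        cache[comp_id] = graph_from_definition(d[comp_id])
    return cache[comp_id]


# ---------------------------------------------------------------------------
# composite score

def _pct(matched: int, eligible: int) -> float | str:
    if eligible == 0:
        return NA
    return round(100.0 * matched / eligible, 1)


def score_graphs(inst_g: MolecularGraph, def_g: MolecularGraph,
                 mapping: dict[str, str]) -> CompositeScore:
    """Five-category comparison of a subject graph against a reference
    definition graph under an atom mapping (subject -> reference).

    Denominators come from the reference side; reference atoms left unmapped
    (missing in the subject) count as non-matching in their categories.
    """
    for ia, da in mapping.items():
        if ia not in inst_g.g.nodes:
            raise KeyError(f"mapping references unknown instance atom {ia!r}")
        if da not in def_g.g.nodes:
            raise KeyError(f"mapping references unknown definition atom {da!r}")
    inv = {v: k for k, v in mapping.items()}
    def_heavy = def_g.heavy_atoms()

    heavy_elig = len(def_heavy)
    heavy_match = sum(
        1 for da in def_heavy
        if da in inv and inst_g.element(inv[da]) == def_g.element(da))

    chiral_def = [da for da in def_heavy if def_g.g.nodes[da]["chiral"]]
    chiral_match = sum(
        1 for da in chiral_def
        if da in inv and inst_g.g.nodes[inv[da]]["chiral"])

    both_chiral = [da for da in chiral_def
                   if da in inv and inst_g.g.nodes[inv[da]]["chiral"]]
    hand_match = sum(
        1 for da in both_chiral
        if inst_g.g.nodes[inv[da]]["parity"] == def_g.g.nodes[da]["parity"])

    arom_def = [da for da in def_heavy if def_g.g.nodes[da]["aromatic"]]
    arom_match = sum(
        1 for da in arom_def
        if da in inv and inst_g.g.nodes[inv[da]]["aromatic"])

    order_match = sum(
        1 for da in def_heavy
        if da in inv and inst_g.incident_order_multiset(inv[da])
        == def_g.incident_order_multiset(da))

    return CompositeScore(
        heavy_atoms_pct=_pct(heavy_match, heavy_elig),
        chiral_count_pct=_pct(chiral_match, len(chiral_def)),
        handedness_pct=_pct(hand_match, len(both_chiral)),
        aromatic_pct=_pct(arom_match, len(arom_def)),
        bond_order_pct=_pct(order_match, heavy_elig),
    )


def composite_score(inst: ComponentInstance, comp: ComponentDefinition,
                    mapping: dict[str, str]) -> CompositeScore:
    return score_graphs(inst.graph, graph_from_definition(comp), mapping)


# ---------------------------------------------------------------------------
# ranking and status

def rank_candidates(candidates: list[Candidate],
                    deposited_id: str) -> list[Candidate]:
    """Deterministic descending sort: (1) deposited-id equality with exact
    chemistry, (2) mean of defined categories, (3) handedness, (4) comp_id."""

    def sort_key(c: Candidate):
        exact_id = c.comp_id == deposited_id and c.score.is_exact()
        hand = c.score.handedness_pct
        hand_val = -1.0 if hand == NA else float(hand)
        return (-int(exact_id), -c.score.mean_defined(), -hand_val, c.comp_id)

    return sorted(candidates, key=sort_key)


def assign_status(result: MatchResult, deposited_id: str) -> MatchResult:
    """passed: exact chemistry and correct id; close match: candidates exist
    but chemistry or id differ; no match: no candidate at all."""
    top = result.top_hit
    if top is None:
        result.status = "no match"
    elif top.score.is_exact() and top.comp_id == deposited_id:
        result.status = "passed"
    else:
        result.status = "close match"
    return result


def match_instance(inst: ComponentInstance, d: Dictionary,
                   k: int = 10) -> MatchResult:
    """Search, score, rank and triage one instance."""
    result = MatchResult(instance=inst)
    for comp_id, mapping in find_candidates(inst, d, k=k):
        score = score_graphs(inst.graph, _definition_graph(d, comp_id),
                             mapping)
        result.candidates.append(Candidate(comp_id, score, mapping))
    result.candidates = rank_candidates(result.candidates, inst.comp_id)
    return assign_status(result, inst.comp_id)


def match_entry(entry: StructureEntry, d: Dictionary,
                include_waters: bool = False, k: int = 10,
                config=None) -> list[MatchResult]:
    return [match_instance(inst, d, k=k)
            for inst in extract_instances(entry, d, include_waters, config)]


# ---------------------------------------------------------------------------
# nomenclature standardization

def standardize_nomenclature(entry: StructureEntry,
                             results: list[MatchResult],
                             ) -> tuple[StructureEntry, list[dict]]:
    """Rewrite instance atom names and comp_ids from the top-hit mapping.

    Coordinates are untouched; cap (leaving-group) atoms added during
    environment augmentation are never written back. Returns the updated
    entry and a rename log. Any unresolved instance is an error: a new
    definition must be created first.
    """
    import copy

    unresolved = [r.instance.label(i + 1) for i, r in enumerate(results)
                  if r.status == "no match"]
    if unresolved:
        raise ValueError(
            "cannot standardize entry with unmatched instances "
            f"({', '.join(unresolved)}); create new definitions first")
    entry = copy.deepcopy(entry)
    log: list[dict] = []
    by_key = {r.instance.key: r for r in results}
    for res in entry.residues:
        r = by_key.get((res.chain, res.seqnum, res.icode))
        if r is None or r.top_hit is None:
            continue
        mapping = r.top_hit.mapping
        caps = set(r.instance.cap_atoms)
        new_atoms = []
        for a in res.atoms:
            target = mapping.get(a.name, a.name)
            if a.name in caps:
                continue
            if target != a.name:
                log.append({"chain": res.chain, "seqnum": res.seqnum,
                            "kind": "atom", "old": a.name, "new": target})
            new_atoms.append(
                a if target == a.name else
                type(a)(name=target, element=a.element, xyz=a.xyz,
                        occupancy=a.occupancy, altloc=a.altloc))
        res.atoms = new_atoms
        if res.comp_id != r.top_hit.comp_id:
            log.append({"chain": res.chain, "seqnum": res.seqnum,
                        "kind": "comp_id", "old": res.comp_id,
                        "new": r.top_hit.comp_id})
            res.comp_id = r.top_hit.comp_id
    return entry, log


# ---------------------------------------------------------------------------
# id assignment and redundancy

_ALPHABET = string.digits + string.ascii_uppercase


def assign_new_id(d: Dictionary, requested: str | None = None) -> str:
    """A free component id: the requested one if available, else the
    lexicographically first unused 3-character code over 0-9A-Z."""
    if requested is not None:
        requested = requested.upper()
        if requested in d:
            raise ValueError(f"requested id {requested!r} is already in use")
        return requested
    for code in itertools.product(_ALPHABET, repeat=3):
        cid = "".join(code)
        if cid not in d:
            return cid
    raise RuntimeError("component id space exhausted")


def redundancy_check(new_def: ComponentDefinition, d: Dictionary) -> list[str]:
    """comp_ids of existing definitions chemically identical to ``new_def``
    (graph-isomorphic with every defined category scoring 100)."""
    new_def.validate()
    new_g = graph_from_definition(new_def)
    dup: list[str] = []
    for comp_id in d.by_element_counts(new_g.element_counts()):
        def_g = _definition_graph(d, comp_id)
        mapping = _best_mapping(new_g, def_g, subgraph=False)
        if mapping is None:
            continue
        if score_graphs(new_g, def_g, mapping).is_exact():
            dup.append(comp_id)
    return dup
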