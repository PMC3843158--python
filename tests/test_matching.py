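"""Candidate search, composite scoring, ranking, status, nomenclature."""

import pytest

from conftest import brute_force_isomorphisms, instance_from_definition, \
    single_instance
from ccakit.ccdio import AtomDef, BondDef, ComponentDefinition, Dictionary
from ccakit.matching import (NA, assign_new_id, extract_instances,
                             find_candidates, match_instance,
                             redundancy_check, score_graphs,
                             standardize_nomenclature)
from ccakit.perception import graph_from_definition


def test_fourteen_instances_extracted(fig_entry, toy_dict):
    instances = extract_instances(fig_entry, toy_dict)
    assert len(instances) == 14


def test_no_hetero_residues_yields_no_instances(toy_dict):
    from ccakit.ccdio import EntryAtom, Residue, StructureEntry

    entry = StructureEntry(residues=[Residue(
        chain="A", seqnum=1, comp_id="ALA", polymer=True,
        atoms=[EntryAtom("CA", "C", (0, 0, 0))])])
    assert extract_instances(entry, toy_dict) == []


def test_waters_skipped_unless_requested(toy_dict):
    from ccakit.ccdio import EntryAtom, Residue, StructureEntry

    entry = StructureEntry(residues=[
        Residue(chain="W", seqnum=1, comp_id="HOH", polymer=False,
                atoms=[EntryAtom("O", "O", (0, 0, 0))]),
        Residue(chain="C", seqnum=2, comp_id="ZN", polymer=False,
                atoms=[EntryAtom("ZN", "Zn", (9, 9, 9))])])
    assert len(extract_instances(entry, toy_dict)) == 1
    assert len(extract_instances(entry, toy_dict, include_waters=True)) == 2


def test_linked_sugars_stay_separate_but_share_group(toy_dict):
    """Two hetero residues joined by a perceived covalent bond remain two
    instances carrying linkage records and one group id."""
    from ccakit.ccdio import EntryAtom, Residue, StructureEntry

    man = toy_dict["MAN"]
    atoms1 = [EntryAtom(a.name, a.element, a.xyz)
              for a in man.heavy_atoms()]
    # second copy shifted so its O1 sits 1.43 A from the first copy's C6
    import numpy as np

    pos = {a.name: np.array(a.xyz) for a in man.heavy_atoms()}
    shift = (pos["C6"] + np.array([1.43, 0, 0])) - pos["O1"]
    atoms2 = [EntryAtom(a.name, a.element,
                        tuple(np.array(a.xyz) + shift))
              for a in man.heavy_atoms()]
    entry = StructureEntry(residues=[
        Residue(chain="C", seqnum=1, comp_id="MAN", atoms=atoms1),
        Residue(chain="C", seqnum=2, comp_id="MAN", atoms=atoms2)])
    instances = extract_instances(entry, toy_dict)
    assert len(instances) == 2
    assert instances[0].group_id == instances[1].group_id
    assert any(l.kind == "covalent" for l in instances[0].linkages)


def test_anomer_pair_both_candidates(toy_dict):
    _, inst = single_instance([("NAG", 1, ("flatten_chiral", "C1"))], 3,
                              toy_dict)
    ids = {cid for cid, _ in find_candidates(inst, toy_dict)}
    assert {"NAG", "NDG"} <= ids


def test_metal_instance_matches_metal_definitions(toy_dict):
    _, inst = single_instance([("ZN", 1, None)], 3, toy_dict)
    ids = [cid for cid, _ in find_candidates(inst, toy_dict)]
    assert ids == ["ZN"]


def test_unmatchable_graph_yields_no_candidates(toy_dict):
    from ccakit.matching import ComponentInstance
    from ccakit.perception import perceive_all

    inst = ComponentInstance(chain="C", seqnum=1, icode="", comp_id="XXX")
    # a P-P-P chain exists nowhere in the toy dictionary
    inst.graph = perceive_all([("P", (0, 0, 0)), ("P", (2.2, 0, 0)),
                               ("P", (4.4, 0, 0))])
    result = match_instance(inst, toy_dict)
    assert result.candidates == [] and result.status == "no match"


def test_flattened_anomeric_carbon_scores_eighty(toy_dict):
    _, inst = single_instance([("NAG", 1, ("flatten_chiral", "C1"))], 3,
                              toy_dict)
    r = match_instance(inst, toy_dict)
    nag = next(c for c in r.candidates if c.comp_id == "NAG")
    assert nag.score.chiral_count_pct == 80.0
    assert nag.score.heavy_atoms_pct == 100.0
    assert nag.score.bond_order_pct == 100.0
    assert r.status == "close match"


def test_inverted_parity_keeps_count_drops_handedness(toy_dict):
    _, inst = single_instance([("NAG", 1, ("invert_parity", "C1"))], 3,
                              toy_dict)
    r = match_instance(inst, toy_dict)
    nag = next(c for c in r.candidates if c.comp_id == "NAG")
    assert nag.score.chiral_count_pct == 100.0
    assert nag.score.handedness_pct == 80.0
    # the epimer definition is the exact hit
    assert r.top_hit.comp_id == "NDG" and r.top_hit.score.is_exact()


@pytest.mark.parametrize("cid", ["GLY", "ALA", "PRO", "LYS", "MAN", "NAG",
                                 "NDG", "MES", "BNZ", "PYR", "CHX", "ZN",
                                 "CLT", "LPR", "GGG"])
def test_every_definition_self_matches_at_100(toy_dict, cid):
    inst = instance_from_definition(toy_dict[cid])
    r = match_instance(inst, toy_dict)
    assert r.status == "passed"
    assert r.top_hit.comp_id == cid
    assert r.top_hit.score.is_exact()


def test_scores_invariant_under_atom_relabeling(toy_dict):
    r1 = match_instance(instance_from_definition(toy_dict["NAG"]), toy_dict)
    r2 = match_instance(
        instance_from_definition(toy_dict["NAG"], rename=True), toy_dict)
    assert r2.top_hit.comp_id == "NAG"
    assert r1.top_hit.score == r2.top_hit.score


def test_chiral_count_monotone_under_additional_flattening(toy_dict):
    """Flattening one more stereocenter never raises the chiral-center
    category."""
    perts = []
    last = 101.0
    for atom in ("C1", "C3", "C4"):
        perts.append(("flatten_chiral", atom))
        _, inst = single_instance([("NAG", 1, list(perts))], 3, toy_dict)
        r = match_instance(inst, toy_dict)
        nag = next(c for c in r.candidates if c.comp_id == "NAG")
        assert nag.score.chiral_count_pct < last
        last = nag.score.chiral_count_pct


def test_status_close_match_on_relabeled_id(toy_dict):
    _, inst = single_instance([("NAG", 1, ("relabel_id", "GG1"))], 3,
                              toy_dict)
    r = match_instance(inst, toy_dict)
    assert r.status == "close match"
    assert r.top_hit.comp_id == "NAG" and r.top_hit.score.is_exact()


def test_ranking_is_deterministic_with_lexicographic_ties(toy_dict):
    """The flattened anomeric instance ties its two anomer candidates; the
    lexicographically smaller id wins."""
    _, inst = single_instance([("NAG", 1, ("flatten_chiral", "C1"))], 3,
                              toy_dict)
    r = match_instance(inst, toy_dict)
    assert [c.comp_id for c in r.candidates[:2]] == ["NAG", "NDG"]


def test_standardize_renames_atoms_and_ids(toy_dict):
    entry, _ = single_instance([("NAG", 1, ("rename_atoms",))], 3, toy_dict)
    results = [match_instance(i, toy_dict)
               for i in extract_instances(entry, toy_dict)]
    new_entry, log = standardize_nomenclature(entry, results)
    res = [r for r in new_entry.residues if not r.polymer][0]
    assert {a.name for a in res.atoms} == \
        {a.name for a in toy_dict["NAG"].heavy_atoms()}
    assert log, "renames must be logged"
    # idempotence on an already standard entry
    results2 = [match_instance(i, toy_dict)
                for i in extract_instances(new_entry, toy_dict)]
    final, log2 = standardize_nomenclature(new_entry, results2)
    assert log2 == []


def test_standardize_refuses_unmatched_instances(toy_dict):
    from ccakit.matching import ComponentInstance, MatchResult
    from ccakit.perception import perceive_all

    entry, _ = single_instance([("ZN", 1, None)], 3, toy_dict)
    inst = ComponentInstance(chain="C", seqnum=1001, icode="", comp_id="ZN")
    inst.graph = perceive_all([("Zn", (0, 0, 0))])
    bad = MatchResult(instance=inst)  # no candidates -> no match
    with pytest.raises(ValueError, match="new definition"):
        standardize_nomenclature(entry, [bad])


def test_assign_new_id_rules(toy_dict):
    zn = ComponentDefinition("000", atoms=[AtomDef("ZN", "Zn")])
    d = Dictionary([zn])
    assert assign_new_id(d) == "001"
    assert assign_new_id(toy_dict, "R12") == "R12"
    with pytest.raises(ValueError, match="in use"):
        assign_new_id(d, "000")


def test_redundancy_check_sees_through_renaming(toy_dict):
    gly = toy_dict["GLY"]
    ren = {a.name: f"Q{i}" for i, a in enumerate(gly.atoms)}
    dup = ComponentDefinition(
        "ZZZ",
        atoms=[AtomDef(ren[a.name], a.element, a.charge, a.aromatic,
                       a.stereo, a.xyz, a.leaving) for a in gly.atoms],
        bonds=[BondDef(ren[b.atom1], ren[b.atom2], b.order, b.aromatic)
               for b in gly.bonds])
    assert redundancy_check(dup, toy_dict) == ["GLY"]
    # one bond order changed -> chemistry differs -> clean
    altered = ComponentDefinition(
        "ZZZ", atoms=dup.atoms,
        bonds=[BondDef(b.atom1, b.atom2,
                       "single" if b.order == "double" else b.order,
                       b.aromatic) for b in dup.bonds])
    assert redundancy_check(altered, toy_dict) == []


def test_novel_graph_is_not_redundant(toy_dict):
    novel = ComponentDefinition(
        "NVL",
        atoms=[AtomDef("P1", "P", xyz=(0, 0, 0)),
               AtomDef("P2", "P", xyz=(2.2, 0, 0))],
        bonds=[BondDef("P1", "P2")])
    assert redundancy_check(novel, toy_dict) == []


@pytest.mark.parametrize("cid", ["GLY", "ALA", "PRO", "LYS", "MES", "BNZ",
                                 "PYR", "CHX", "ZN", "MAN"])
def test_matcher_agrees_with_brute_force_oracle(toy_dict, cid):
    """Candidate sets and mapping quality equal an exhaustive all-bijections
    matcher on every fixture with at most 12 heavy atoms."""
    comp = toy_dict[cid]
    assert len(comp.heavy_atoms()) <= 12
    inst = instance_from_definition(comp, rename=True)
    vf2_ids = {c for c, _ in find_candidates(inst, toy_dict, k=99)}
    oracle_ids = set()
    for other in toy_dict:
        gd = graph_from_definition(toy_dict[other])
        if brute_force_isomorphisms(inst.graph, gd):
            oracle_ids.add(other)
    assert vf2_ids == oracle_ids
    # the returned mapping achieves the oracle's best objective
    r = match_instance(inst, toy_dict)
    top = r.top_hit
    gd = graph_from_definition(toy_dict[top.comp_id])

    def objective(mapping):
        s = score_graphs(inst.graph, gd, mapping)
        return (s.handedness_pct if s.handedness_pct != NA else -1,
                s.bond_order_pct)

    best = max(objective(m)
               for m in brute_force_isomorphisms(inst.graph, gd))
    assert objective(top.mapping) == best


def test_score_with_unknown_mapping_atom_raises(toy_dict):
    inst = instance_from_definition(toy_dict["GLY"])
    gd = graph_from_definition(toy_dict["GLY"])
    with pytest.raises(KeyError):
        score_graphs(inst.graph, gd, {"NOPE": "N"})
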