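"""Peptide-like decomposition: cut selection, capping, ordering, writeback."""

import pytest

from conftest import single_instance
from ccakit.chopper import (apply_chop_to_entry, chop, order_sequence,
                            select_cleavage_bonds)
from ccakit.matching import ComponentInstance, match_instance
from ccakit.perception import perceive_all


@pytest.fixture()
def ggg(toy_dict):
    return single_instance([("GGG", 1, None)], 4, toy_dict)


@pytest.fixture()
def lpr(toy_dict):
    return single_instance([("LPR", 1, None)], 4, toy_dict)


def test_triglycine_selects_two_amides(ggg):
    _, inst = ggg
    assert select_cleavage_bonds(inst.graph) == [("C1", "N2"), ("C2", "N3")]


def test_lisinopril_selects_amine_and_amide(lpr):
    _, inst = lpr
    bonds = select_cleavage_bonds(inst.graph)
    assert sorted(bonds) == [("C2", "NL"), ("CL", "NP")]


@pytest.mark.parametrize("cid", ["GLY", "ALA", "PRO", "LYS"])
def test_free_amino_acid_selects_nothing(toy_dict, cid):
    _, inst = single_instance([(cid, 1, None)], 4, toy_dict)
    assert select_cleavage_bonds(inst.graph) == []


def test_triglycine_chops_into_three_glycines(ggg, toy_dict):
    _, inst = ggg
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), toy_dict)
    assert len(dec.fragments) == 3
    for frag in dec.fragments:
        assert frag.top_id == "GLY"
        assert frag.match.top_hit.score.is_exact()


def test_lisinopril_chops_to_clt_lys_pro_in_order(lpr, toy_dict):
    _, inst = lpr
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), toy_dict)
    assert [f.top_id for f in dec.fragments] == ["CLT", "LYS", "PRO"]
    assert all(f.is_matched() for f in dec.fragments)


def test_chop_with_no_bonds_is_identity(ggg, toy_dict):
    _, inst = ggg
    dec = chop(inst.graph, [], toy_dict)
    assert len(dec.fragments) == 1
    assert sorted(dec.fragments[0].members) == \
        sorted(inst.graph.heavy_atoms())


def test_cutting_a_ring_bond_alone_is_rejected(toy_dict):
    _, inst = single_instance([("CHX", 1, None)], 4, toy_dict)
    with pytest.raises(ValueError, match="C1-C2|C2-C1"):
        chop(inst.graph, [("C1", "C2")], toy_dict)


def test_heavy_atom_conservation_under_chopping(ggg, lpr, toy_dict):
    """Fragment heavy atoms sum to parent heavy atoms plus one oxygen per
    -OH cap; -H caps add none."""
    for _, inst in (ggg, lpr):
        bonds = select_cleavage_bonds(inst.graph)
        dec = chop(inst.graph, bonds, toy_dict)
        total = sum(len(f.graph.heavy_atoms()) for f in dec.fragments)
        n_oh = sum(1 for f in dec.fragments for c in f.cap_atoms
                   if c.startswith("OXC"))
        assert total == len(inst.graph.heavy_atoms()) + n_oh
        assert n_oh == len(bonds)


def test_fragment_members_partition_parent(lpr, toy_dict):
    _, inst = lpr
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), toy_dict)
    members = [a for f in dec.fragments for a in f.members]
    assert sorted(members) == sorted(inst.graph.heavy_atoms())


def test_ordering_modes(ggg, toy_dict):
    _, inst = ggg
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), toy_dict)
    base = [tuple(f.members) for f in dec.fragments]
    # first fragment holds the free amine N1
    assert any("N1" in m for m in dec.fragments[0].members)
    rev = order_sequence(dec, "reverse")
    assert [tuple(f.members) for f in rev.fragments] == base[::-1]
    back = order_sequence(rev, "reverse")
    assert [tuple(f.members) for f in back.fragments] == base
    rot = order_sequence(back, ("rotate", 1))
    assert [tuple(f.members) for f in rot.fragments] == base[1:] + base[:1]


def test_apply_polymer_mode_builds_sequential_residues(ggg, toy_dict):
    entry, inst = ggg
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), toy_dict)
    new_entry = apply_chop_to_entry(entry, inst.key, dec, "polymer")
    chain_res = [r for r in new_entry.residues if r.chain == inst.chain]
    assert [r.comp_id for r in chain_res] == ["GLY", "GLY", "GLY"]
    assert [r.seqnum for r in chain_res] == \
        [inst.seqnum, inst.seqnum + 1, inst.seqnum + 2]
    assert all(r.polymer for r in chain_res)
    # cap atoms never reach the entry; re-matching each residue against its
    # fragment top hit is exact after re-capping the cut bonds
    for res, frag in zip(chain_res, dec.fragments):
        assert {a.name for a in res.atoms} <= \
            {a.name for a in toy_dict["GLY"].heavy_atoms()}


def test_apply_subcomponent_mode_records_sequence(lpr, toy_dict):
    entry, inst = lpr
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), toy_dict)
    new_entry = apply_chop_to_entry(entry, inst.key, dec, "subcomponent")
    assert new_entry.subcomponents[inst.key] == ["CLT", "LYS", "PRO"]
    assert new_entry.residue(*inst.key).comp_id == "LPR"


def test_apply_refuses_unmatched_fragments(ggg, toy_dict):
    from ccakit.ccdio import Dictionary

    entry, inst = ggg
    empty = Dictionary()
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), empty)
    with pytest.raises(ValueError, match="no exact dictionary match"):
        apply_chop_to_entry(entry, inst.key, dec, "polymer")


def test_rechopped_polymer_residues_match_fragment_hits(ggg, toy_dict):
    """After writing the polymer representation, each residue's atoms (with
    the cut bonds re-capped) still score 100 against the fragment top hit."""
    entry, inst = ggg
    dec = chop(inst.graph, select_cleavage_bonds(inst.graph), toy_dict)
    new_entry = apply_chop_to_entry(entry, inst.key, dec, "polymer")
    chain_res = [r for r in new_entry.residues if r.chain == inst.chain]
    for res, frag in zip(chain_res, dec.fragments):
        # rebuild the capped fragment from entry coordinates
        atoms = [(a.name, a.element, a.xyz) for a in res.atoms]
        for cap in frag.cap_atoms:
            g = frag.graph
            atoms.append((cap, g.element(cap), tuple(g.xyz(cap))))
        probe = ComponentInstance(chain="Z", seqnum=0, icode="",
                                  comp_id=res.comp_id)
        probe.graph = perceive_all(atoms)
        r = match_instance(probe, toy_dict)
        assert r.top_hit.comp_id == frag.top_id
        assert r.top_hit.score.is_exact()
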