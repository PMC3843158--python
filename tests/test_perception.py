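"""Geometric perception: bonds, hybridization, parity, aromaticity, ranks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccakit.perception import (assign_handedness, graph_from_definition,
                               perceive_all, perceive_bonds,
                               perceive_hybridization)

TETRAHEDRON = [
    ("C0", "C", (0.0, 0.0, 0.0)),
    ("N1", "N", (1.47, 0.0, 0.0)),
    ("C2", "C", (-0.51, 1.45, 0.0)),
    ("O3", "O", (-0.51, -0.72, 1.24)),
]


def test_bond_within_radius_sum():
    g = perceive_bonds([("C", (0, 0, 0)), ("C", (1.54, 0, 0))])
    assert g.g.number_of_edges() == 1
    assert g.bond_label(*list(g.g.edges)[0]) == "single"


def test_no_bond_at_three_angstroms():
    g = perceive_bonds([("C", (0, 0, 0)), ("C", (3.0, 0, 0))])
    assert g.g.number_of_edges() == 0


def test_metal_contact_is_coordination_not_bond():
    g = perceive_bonds([("Zn", (0, 0, 0)), ("O", (2.1, 0, 0))])
    assert g.g.number_of_edges() == 0
    assert len(g.coordination) == 1
    (a, b, d) = g.coordination[0]
    assert d == pytest.approx(2.1)


def test_unknown_element_raises():
    with pytest.raises(KeyError):
        perceive_bonds([("Xq", (0, 0, 0))])


def test_tetrahedral_center_is_sp3_flattened_is_sp2():
    g = perceive_all(TETRAHEDRON)
    assert g.g.nodes["C0"]["hyb"] == "sp3"
    flat = [(n, e, (x, y, 0.0)) for n, e, (x, y, z) in TETRAHEDRON]
    g2 = perceive_all(flat)
    assert g2.g.nodes["C0"]["hyb"] == "sp2"
    assert not g2.g.nodes["C0"]["chiral"]


def test_two_neighbor_linear_is_sp():
    g = perceive_bonds([("O", (-1.16, 0, 0)), ("C", (0, 0, 0)),
                        ("O", (1.16, 0, 0))])
    perceive_hybridization(g)
    assert g.g.nodes["C2"]["hyb"] == "sp"


def test_mirror_image_flips_parity():
    g = perceive_all(TETRAHEDRON)
    mirrored = [(n, e, (x, y, -z)) for n, e, (x, y, z) in TETRAHEDRON]
    g2 = perceive_all(mirrored)
    assert g.g.nodes["C0"]["chiral"] and g2.g.nodes["C0"]["chiral"]
    assert g.g.nodes["C0"]["parity"] == -g2.g.nodes["C0"]["parity"]


def test_equal_rank_neighbors_disqualify_center():
    # two identical methyl-like carbons around the center: pro-chiral
    atoms = [
        ("C0", "C", (0.0, 0.0, 0.0)),
        ("N1", "N", (1.47, 0.0, 0.0)),
        ("C2", "C", (-0.51, 1.45, 0.0)),
        ("C3", "C", (-0.51, -0.72, 1.24)),
    ]
    g = perceive_all(atoms)
    assert not g.g.nodes["C0"]["chiral"]
    assert g.g.nodes["C0"]["parity"] == 0


def test_benzene_aromatic_cyclohexane_not(toy_dict):
    for cid, n_arom in (("BNZ", 6), ("PYR", 6), ("CHX", 0)):
        comp = toy_dict[cid]
        g = perceive_all([(a.name, a.element, a.xyz)
                          for a in comp.heavy_atoms()])
        assert sum(g.g.nodes[x]["aromatic"] for x in g.g.nodes) == n_arom, cid


def test_definition_graph_reports_stereocenters(toy_dict):
    g = graph_from_definition(toy_dict["NAG"])
    centers = [n for n in g.g.nodes if g.g.nodes[n]["chiral"]]
    assert sorted(centers) == ["C1", "C2", "C3", "C4", "C5"]
    zn = graph_from_definition(toy_dict["ZN"])
    assert zn.g.number_of_nodes() == 1 and zn.g.number_of_edges() == 0


def test_stereo_flag_on_underconnected_atom_rejected(toy_dict):
    import copy

    from ccakit.ccdio import AtomDef

    comp = copy.deepcopy(toy_dict["GLY"])
    comp.atoms = [
        AtomDef(a.name, a.element, a.charge, a.aromatic,
                "S" if a.name == "O" else a.stereo, a.xyz, a.leaving)
        for a in comp.atoms]
    with pytest.raises(ValueError, match="stereo"):
        graph_from_definition(comp)


@pytest.mark.parametrize("cid", ["GLY", "ALA", "PRO", "LYS", "MAN", "NAG",
                                 "NDG", "MES", "BNZ", "PYR", "CHX", "CLT",
                                 "LPR", "GGG"])
def test_perception_reproduces_definition_graph(toy_dict, cid):
    """Perceiving a definition's own idealized coordinates recovers its
    stored heavy-atom edges, orders, chiral centers and parities."""
    comp = toy_dict[cid]
    g = perceive_all([(a.name, a.element, a.xyz)
                      for a in comp.heavy_atoms()])
    gd = graph_from_definition(comp)
    assert {frozenset(e) for e in g.g.edges} == \
        {frozenset((b.atom1, b.atom2)) for b in comp.bonds}
    for b in comp.bonds:
        assert g.bond_label(b.atom1, b.atom2) == \
            gd.bond_label(b.atom1, b.atom2)
    for n in gd.g.nodes:
        assert g.g.nodes[n]["chiral"] == gd.g.nodes[n]["chiral"]
        assert g.g.nodes[n]["parity"] == gd.g.nodes[n]["parity"]
        assert g.g.nodes[n]["aromatic"] == gd.g.nodes[n]["aromatic"]


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_relabeling_invariance(seed):
    """Permuting atom input order changes no derived attribute multiset."""
    from ccakit.fixtures import make_toy_dictionary

    comp = make_toy_dictionary()["NAG"]
    atoms = [(a.name, a.element, a.xyz) for a in comp.heavy_atoms()]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(atoms))
    shuffled = [atoms[i] for i in perm]
    g1, g2 = perceive_all(atoms), perceive_all(shuffled)
    for attr in ("hyb", "chiral", "parity", "aromatic", "rank"):
        m1 = sorted(str(g1.g.nodes[n][attr]) for n in g1.g.nodes)
        m2 = sorted(str(g2.g.nodes[n][attr]) for n in g2.g.nodes)
        assert m1 == m2, attr
    # same attributes on the same atom names, not just same multisets
    for n in g1.g.nodes:
        assert g1.g.nodes[n]["parity"] == g2.g.nodes[n]["parity"]


@pytest.mark.parametrize("cid", ["MAN", "NAG", "ALA", "LYS", "PRO", "LPR"])
def test_reflection_flips_every_parity(toy_dict, cid):
    comp = toy_dict[cid]
    atoms = [(a.name, a.element, a.xyz) for a in comp.heavy_atoms()]
    mirrored = [(n, e, (x, y, -z)) for n, e, (x, y, z) in atoms]
    g1, g2 = perceive_all(atoms), perceive_all(mirrored)
    flipped = 0
    for n in g1.g.nodes:
        assert g1.g.nodes[n]["chiral"] == g2.g.nodes[n]["chiral"]
        if g1.g.nodes[n]["chiral"]:
            assert g1.g.nodes[n]["parity"] == -g2.g.nodes[n]["parity"]
            flipped += 1
        assert g1.g.nodes[n]["aromatic"] == g2.g.nodes[n]["aromatic"]
    assert flipped > 0
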