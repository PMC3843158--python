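"""Definition editing: implicit hydrogens, formulas, commits."""

import pytest

from ccakit.ccdio import AtomDef, BondDef, ComponentDefinition, Dictionary
from ccakit.edit import (add_atom, apply_edit_script, commit_definition,
                         compute_formula, implicit_hydrogens,
                         recompute_descriptors, set_bond_order)


def test_add_carbon_updates_counts_and_formula(toy_dict):
    chx = toy_dict["CHX"]
    out = add_atom(chx, "C16", "C", "C2")
    assert len(out.heavy_atoms()) == len(chx.heavy_atoms()) + 1
    assert out.formula == "C7 H14"
    assert any({b.atom1, b.atom2} == {"C2", "C16"} for b in out.bonds)


def test_add_duplicate_name_rejected(toy_dict):
    with pytest.raises(ValueError, match="already exists"):
        add_atom(toy_dict["CHX"], "C1", "C", "C2")


def test_explicit_hydrogen_decrements_implicit_count(toy_dict):
    chx = toy_dict["CHX"]
    assert implicit_hydrogens(chx, "C1") == 2
    out = add_atom(chx, "H1", "H", "C1")
    assert implicit_hydrogens(out, "C1") == 1
    assert out.formula == "C6 H12"  # total H unchanged


def test_bond_order_change_adjusts_hydrogens_both_ways(toy_dict):
    """Single->double removes one implicit H at each end; double->single
    restores them."""
    chx = add_atom(toy_dict["CHX"], "C16", "C", "C2")
    up = set_bond_order(chx, "C1", "C2", "double")
    assert implicit_hydrogens(up, "C1") == 1
    assert implicit_hydrogens(up, "C2") == 0
    down = set_bond_order(up, "C1", "C2", "single")
    assert implicit_hydrogens(down, "C1") == 2
    assert implicit_hydrogens(down, "C2") == 1
    assert down.formula == up.formula.replace("H12", "H14")


def test_valence_overflow_rejected(toy_dict):
    chx = add_atom(toy_dict["CHX"], "C16", "C", "C2")
    up = set_bond_order(chx, "C1", "C2", "double")
    with pytest.raises(ValueError, match="overflow"):
        set_bond_order(up, "C2", "C3", "double")


def test_nonexistent_bond_rejected(toy_dict):
    with pytest.raises(ValueError, match="no bond"):
        set_bond_order(toy_dict["CHX"], "C1", "C4", "double")


def test_glycine_formula_from_valence_model(toy_dict):
    assert compute_formula(toy_dict["GLY"]) == "C2 H5 N O2"
    assert compute_formula(toy_dict["ZN"]) == "Zn"


def test_recompute_descriptors_idempotent(toy_dict):
    edited = set_bond_order(add_atom(toy_dict["CHX"], "C16", "C", "C2"),
                            "C1", "C2", "double")
    once = recompute_descriptors(edited)
    twice = recompute_descriptors(once)
    assert once.formula == twice.formula
    assert once.atoms == twice.atoms
    assert once.bonds == twice.bonds


def test_recompute_invariant_under_atom_reorder(toy_dict):
    import copy

    comp = copy.deepcopy(toy_dict["GLY"])
    shuffled = copy.deepcopy(comp)
    shuffled.atoms = shuffled.atoms[::-1]
    assert recompute_descriptors(comp).formula == \
        recompute_descriptors(shuffled).formula


def test_commit_novel_and_reject_duplicates(toy_dict):
    d = Dictionary([toy_dict[cid] for cid in toy_dict])
    novel = ComponentDefinition(
        "NVL",
        atoms=[AtomDef("P1", "P", xyz=(0, 0, 0)),
               AtomDef("P2", "P", xyz=(2.2, 0, 0))],
        bonds=[BondDef("P1", "P2")])
    commit_definition(d, novel)
    assert "NVL" in d and len(d) == len(toy_dict) + 1
    # renamed copy of an existing definition is chemistry-redundant
    gly = d["GLY"]
    ren = {a.name: f"Q{i}" for i, a in enumerate(gly.atoms)}
    dup = ComponentDefinition(
        "DUP",
        atoms=[AtomDef(ren[a.name], a.element, a.charge, a.aromatic,
                       a.stereo, a.xyz, a.leaving) for a in gly.atoms],
        bonds=[BondDef(ren[b.atom1], ren[b.atom2], b.order, b.aromatic)
               for b in gly.bonds])
    with pytest.raises(ValueError, match="GLY"):
        commit_definition(d, dup)
    # committing the same definition twice fails on the id
    with pytest.raises(ValueError, match="already in dictionary"):
        commit_definition(d, novel)


def test_edit_script_round(toy_dict, tmp_path):
    d = Dictionary([toy_dict["CHX"], toy_dict["ZN"]])
    comp = d["CHX"]
    import copy

    comp = copy.deepcopy(comp)
    comp.comp_id = "R12"
    lines = [
        "addatom C16 C C2",
        "order C1 C2 double",
        "order C2 C3 single  # already single, no-op",
        "commit",
    ]
    d, comp = apply_edit_script(d, comp, lines)
    assert "R12" in d
    assert d["R12"].formula == "C7 H12"


def test_edit_script_bad_command_reports_line(toy_dict):
    with pytest.raises(ValueError, match="line 1"):
        apply_edit_script(Dictionary(), toy_dict["CHX"], ["frobnicate X"])
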