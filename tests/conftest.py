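"""Shared fixtures and the independent brute-force isomorphism oracle."""

from __future__ import annotations

import pytest

from ccakit.fixtures import make_entry, make_toy_dictionary
from ccakit.matching import ComponentInstance
from ccakit.perception import perceive_all


@pytest.fixture(scope="session")
def toy_dict():
    return make_toy_dictionary()


@pytest.fixture(scope="session")
def fig_entry(toy_dict):
    """The 14-component benchmark entry: 2 relabeled mannose-like, 7 intact
    and 1 anomeric-flattened acetylglucosamine-like, 2 sulfonate buffers,
    2 zinc ions."""
    spec = [("MAN", 2, ("relabel_id", "BMA")),
            ("NAG", 7, None),
            ("NAG", 1, ("flatten_chiral", "C1")),
            ("MES", 2, None),
            ("ZN", 2, None)]
    return make_entry(spec, seed=11, dictionary=toy_dict)


def instance_from_definition(comp, comp_id=None, rename=False):
    """Perceive a definition's own idealized coordinates as an instance."""
    atoms = [(a.name, a.element, a.xyz) for a in comp.heavy_atoms()]
    if rename:
        atoms = [(f"X{i + 1}", el, xyz)
                 for i, (_, el, xyz) in enumerate(atoms)]
    inst = ComponentInstance(chain="Z", seqnum=1, icode="",
                             comp_id=comp_id or comp.comp_id)
    inst.graph = perceive_all(atoms)
    return inst


def single_instance(spec, seed, toy_dict):
    """Build a one-instance entry and extract its instance."""
    from ccakit.matching import extract_instances

    entry = make_entry(spec, seed=seed, dictionary=toy_dict)
    instances = extract_instances(entry, toy_dict)
    assert len(instances) >= 1
    return entry, instances[0]


# ---------------------------------------------------------------------------
# brute-force all-bijections matcher (independent of networkx VF2)

def brute_force_isomorphisms(gi, gd) -> list[dict]:
    """Every element-preserving, adjacency-preserving bijection between the
    heavy atoms of two graphs, found by exhaustive backtracking in fixed
    atom order."""
    ai = sorted(gi.heavy_atoms())
    ad = sorted(gd.heavy_atoms())
    if len(ai) != len(ad):
        return []
    results: list[dict] = []

    def extend(i: int, used: set, mapping: dict) -> None:
        if i == len(ai):
            results.append(dict(mapping))
            return
        a = ai[i]
        for b in ad:
            if b in used or gd.element(b) != gi.element(a):
                continue
            if any(gi.g.has_edge(a, prev) != gd.g.has_edge(b, mapping[prev])
                   for prev in ai[:i]):
                continue
            mapping[a] = b
            used.add(b)
            extend(i + 1, used, mapping)
            del mapping[a]
            used.discard(b)

    extend(0, set(), {})
    return results
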