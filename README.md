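# ccakit

Annotation of small-molecule chemical components in macromolecular
structure entries.

Every structure deposited to a macromolecular archive carries, besides its
polymers, a collection of small molecules — sugars, buffers, ions,
inhibitors — each of which must be identified against a *chemical component
dictionary* of reference definitions before the entry can be released.
`ccakit` is a desk-scale library and command-line tool for that curation
task, aimed at structural bioinformaticians and annotation-pipeline
developers. It:

* extracts every component **instance** from an entry (mmCIF or PDB) and
  perceives its chemical graph — bonds, bond orders, hybridization,
  chirality parity, aromaticity — from the 3D coordinates alone;
* searches each instance against a dictionary of `chem_comp` definitions by
  element-labeled graph isomorphism, with a heavy-atom element-count
  prescreen and a subgraph fallback for incomplete ligands;
* scores every candidate with a five-category **composite score** and
  assigns a triage status (*passed* / *close match* / *no match*);
* resolves stereochemistry at covalent attachment points (e.g.
  glycosylation sites) by restoring the **leaving group** the bond consumed;
* **chops** peptide-like ligands into capped, free-neutral subcomponents,
  matches each against the dictionary, and orders them N→C;
* supports dictionary curation: definition editing with an implicit-hydrogen
  valence model, automatic formula updates, new-id assignment and a
  redundancy check before commit.

## The composite score

For an instance *I* mapped onto a candidate definition *D* by an atom
mapping, five categories are each scored as

```
score_cat = 100 × (matched atoms) / (eligible atoms)
```

where the eligible set is taken on the definition side:

| category      | eligible atoms            | an atom matches when                        |
|---------------|---------------------------|---------------------------------------------|
| heavy atoms   | heavy atoms of *D*        | mapped to an instance atom of same element  |
| chiral count  | stereocenters of *D*      | its image is a perceived stereocenter       |
| handedness    | centers chiral on both sides | parities agree                           |
| aromatic      | aromatic atoms of *D*     | its image is aromatic                       |
| bond order    | heavy atoms of *D*        | incident bond-order multisets agree         |

A category with no eligible atoms reports "n/a". An instance is *passed*
only when its best candidate scores 100 (or n/a) everywhere **and** carries
the deposited component id; chemistry-identical instances deposited under
the wrong id are *close matches*.

Handedness is compared convention-independently: both sides compute the
parity of each tetrahedral center as the sign of the determinant of the
vectors to its three highest-ranked neighbors (Morgan-style canonical
ranks), so no CIP machinery is needed and mirror images always disagree.

## Worked example

The package ships a synthetic-data generator: a 15-definition toy
dictionary and perturbable entries built from it.

```sh
cca fixtures make-dict --out toy.cif
cat > spec.json <<'EOF'
[["MAN", 2, ["relabel_id", "BMA"]],
 ["NAG", 7, null],
 ["NAG", 1, ["flatten_chiral", "C1"]],
 ["MES", 2, null],
 ["ZN", 2, null]]
EOF
cca fixtures make-entry --spec spec.json --seed 7 --out entry.pdb
cca report --dict toy.cif --entry entry.pdb
```

prints:

```
instance	top_hit	status	heavy_atoms	chiral_count	handedness	aromatic	bond_order
1_C_BMA_1001	MAN	close match	100	100	100	-	100
2_C_BMA_1002	MAN	close match	100	100	100	-	100
3_C_NAG_1003	NAG	passed	100	100	100	-	100
...
10_C_NAG_1010	NAG	close match	100	80	100	-	100
11_C_MES_1011	MES	passed	100	-	-	-	100
...
14_C_ZN_1014	ZN	passed	100	-	-	-	100
```

Fourteen instances: the two mannose-like residues deposited under a wrong
id are chemically perfect close matches (the annotator's fix is the id
itself); the sugar whose anomeric carbon C1 was flattened to sp2 geometry
loses exactly one of its five stereocenters, hence the 80 in the
chiral-center column; everything else passes.

Chopping a peptidomimetic:

```sh
cca chop --dict toy.cif --entry entry.pdb --residue C/1003
fragments (N->C): CLT LYS PRO
```

— the bundled lisinopril connection table decomposes into its
carboxyphenylbutyl, lysyl and proline subcomponents, each capped back to
its free neutral form (–OH on the carbon side of every cut, –H on the
nitrogen side) and matched exactly.

## Layout

```
src/ccakit/
  ccdio.py        chem_comp dictionary + entry I/O (gemmi-backed)
  perception.py   bonds, orders, hybridization, parity, aromaticity, ranks
  matching.py     candidate search, composite score, status, nomenclature
  environment.py  covalent/coordination linkages, leaving-group capping
  chopper.py      peptide-like decomposition and ordering
  edit.py         definition editing, implicit H, formulas, commit
  fixtures.py     toy dictionary and synthetic entries
  cli.py          `cca` command-line front end
```
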