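# Methods

This note records the models, rules and numerical choices behind `ccakit`,
in the order the pipeline applies them, together with what the synthetic
fixtures do and do not establish about real data.

## Perception from 3D coordinates

An observed instance carries only element symbols and coordinates, so its
chemistry is derived geometrically.

**Bonds.** Atoms *i, j* are bonded iff
`d(i,j) ≤ r_cov(i) + r_cov(j) + t`, with classic single-bond covalent radii
and tolerance `t = 0.40 Å`. Contacts involving a metal (Na, Mg, K, Ca, Mn,
Fe, Co, Ni, Cu, Zn, …) and N/O/S within 3.0 Å are recorded as coordination
contacts and never become graph edges; this keeps metal sites from fusing
their ligands into a single instance.

**Bond orders.** Each perceived bond is classified by the nearest canonical
reference length for its element pair (e.g. C–C 1.54/1.34/1.20 Å for
single/double/triple, C–O 1.43/1.22, S–O 1.58/1.45). Pairs without a table
entry default to single. Nearest-reference classification, rather than fixed
cutoffs, keeps the decision stable under the coordinate noise the fixtures
model and under the bond-length shrinkage that flattening a stereocenter
causes in its incident bonds.

**Hybridization.** A center with three neighbors is sp² iff the sum of its
three bond angles is ≥ 355° (ideal planar 360°, ideal tetrahedral 328.5°;
the threshold is deliberately tolerant of experimental noise), else sp³.
Four neighbors give sp³; two neighbors with an angle ≥ 170° give sp, bent
two-neighbor atoms are treated as sp³; fewer than two neighbors are "other".

**Canonical ranks.** A Morgan-style refinement seeded by (element, heavy
degree) and iterated with sorted neighbor labels to a fixed point. Ranks
are isomorphism-invariant, so corresponding atoms in an instance and in a
matched definition receive the same rank; symmetric atoms tie, and ties are
never broken artificially — a would-be stereocenter with two equal-rank
neighbors is simply declared non-chiral on both sides, consistently.

**Handedness.** A heavy atom is a stereocenter iff it is sp³, has ≥ 3 heavy
neighbors, and those neighbors have pairwise-distinct canonical ranks. Its
parity (±1) is the sign of the determinant of the three vectors to its
highest-ranked neighbors taken in rank order. This is a convention-free
binary configuration: it flips under reflection, and because ranks
correspond under isomorphism, instance and definition parities are directly
comparable without CIP priorities. CIP *labels* (R/S) are out of scope;
the stereo letters stored by the fixture generator are parity tags, not CIP
assignments.

**Aromaticity.** Rings are the minimum cycle basis of the heavy-atom graph
(SSSR), each tested with a Hückel 4n+2 count. Two contribution tables are
needed because instances lack stored orders:

* *definitions* (orders known): ring atom in a ring double bond → 1;
  ring N/O/S without one → 2; ring C with only an exocyclic double bond →
  0; a saturated ring carbon fails the ring;
* *instances* (geometry only): every ring atom must lie within 0.15 Å of
  the best-fit ring plane (a chair deviates by ≈ 0.25 Å, so this cleanly
  separates benzene from cyclohexane); contributions are C → 1 (three-
  coordinate carbons must also be sp²), two-coordinate N → 1
  (pyridine-like), other N and O/S → 2.

All thresholds are overridable through a config mapping.

## Matching and the composite score

Candidates are dictionary definitions whose heavy-atom, element-labeled
graph is isomorphic to the instance graph (VF2), prescreened by equality of
the heavy-atom element-count vector. Bond order, aromaticity and stereo are
deliberately ignored at this stage — the two anomers of a sugar are *both*
candidates, and the composite score, not the matcher, separates them. When
the strict pass finds nothing (incomplete experimental ligands), a subgraph
fallback maps the instance into any definition whose element counts
dominate it; unmapped definition atoms then count against every category.

When a molecule's symmetry admits several isomorphisms, the mapping chosen
is the one maximizing (handedness matches, then bond-order matches), with
remaining ties broken by the lexicographic sequence of mapped definition
canonical ranks and finally by atom names — fully deterministic.

Category denominators are always on the definition side; this is the only
reading under which flattening one of five stereocenters yields exactly
4/5 = 80 %. Hydrogens never participate: "heavy atoms" means non-hydrogen
throughout, and definitions store heavy atoms with implicit hydrogens.

Ranking is by (exact chemistry with the deposited id, mean of defined
categories, handedness, lexicographic id), descending. Status: *passed*
requires an all-100 top hit bearing the deposited id — an id mismatch with
perfect chemistry is a *close match*, since fixing the id is itself an
annotation action; *no match* means the dictionary needs a new definition.

## Environment and leaving groups

Inter-residue contacts of an instance are classified with the same covalent
and metal rules as intra-residue bonds. A covalent attachment consumed a
substituent of the free component (the anomeric hydroxyl, in the
glycosylation case), so the observed instance is one atom short and its
attachment carbon has only three defined neighbors. Capping appends a
surrogate atom along the unit vector toward the former partner — an O at
1.43 Å for a carbon attachment (a leaving hydroxyl with implicit H), an H
at 1.01 Å for N/O attachments — and re-perceives. No existing coordinate
moves. After capping, the attachment center's handedness is defined (unless
its geometry is genuinely planar, in which case sp² still wins) and a
glycosylated sugar matches its free-form definition atom for atom. Cap
atoms are flagged and never written back into the entry.

## Chopping

Cut-point selection targets backbone-forming C–N bonds and is exposed for
manual override. A bond qualifies when it is acyclic and either (a) an
amide — its carbon bears a double-bonded oxygen — or (b) a secondary-amine
backbone bond: the nitrogen is not an amide nitrogen, has at least two
carbon substituents, and the bond's carbon is attached to a carboxyl carbon
(one double-bonded and one single-bonded oxygen). Rule (b) is the minimal
condition that cuts the lisinopril-type N-alkyl backbone at the correct
bond while leaving both the terminal residue of a linear peptide and free
amino acids untouched; requiring only the bond (not the nitrogen) to be
acyclic makes amides to ring nitrogens (proline) cleavable. The rule does
not attempt esters, thioethers or the dehydro/thiazoline chemistry of
complex antibiotics; such bonds can be supplied explicitly.

Cutting removes the bonds, requires every cut to actually separate two
fragments (a ring bond is only legal together with a second opening cut),
caps the carbon side of each cut with –OH and the nitrogen side with –H —
restoring each fragment's free, neutral charge state — and matches every
capped fragment. Fragments are ordered by following the cut bonds C→N from
the unique fragment with a free amine; reversal and rotation handle cyclic
backbones, whose default start is the fragment with the smallest top-hit
id. Writing back supports a true polymer representation (sequential
residues, standardized names, caps dropped) or a single ligand with an
ordered subcomponent list.

## Editing and the valence model

Implicit hydrogens bring each atom's bond-order sum up to its standard
valence — C 4, N 3, O 2, S {2,4,6}, P {3,5}, halogens 1 — adjusted by
formal charge (N⁺ 4, O⁻ 1); aromatic bonds count 1.5. An edit that
overflows every allowed valence is rejected outright. Formulas are
Hill-ordered (C, H, then alphabetical) and include implicit hydrogens.
Atoms added by editing receive placeholder positions from local geometry
(opposite the mean of the anchor's neighbor directions, 1.5 Å); edited
definitions therefore carry approximate, not re-embedded, idealized
coordinates. Committing a definition runs the redundancy check — graph
isomorphism with all five categories at 100 — so an atom-renamed copy of an
existing component is refused while a bond-order variant is accepted.

## The synthetic fixtures

The toy dictionary holds 15 hand-built definitions: glycine, alanine,
proline and lysine in free neutral form; a five-stereocenter pyranose, a
2-acetamido pyranose and its C1 epimer (the anomer pair); a
morpholine-ethanesulfonic acid buffer; benzene, pyridine, cyclohexane; a
zinc ion; 2-hydroxy-4-phenylbutanoic acid; the full lisinopril connection
table; and triglycine as a choppable parent. Geometries are generated from
ideal internal coordinates — tetrahedral 109.47°, trigonal 120°, chair and
regular-polygon ring templates, NeRF chain extension — with every bond laid
down at the same canonical reference length the order classifier uses, so
perception of a definition's own idealized coordinates reproduces its
stored graph exactly. Hill formulas of all fixtures come out chemically
correct (the acetylglucosamine analog is C8 H15 N O6, lisinopril
C21 H31 N3 O5).

Entries place jittered copies (uniform ±0.02 Å per coordinate, seeded; the
generator accepts up to ±0.05 Å but the default leaves order classification
margins of ≥ 0.07 Å) on a 25 Å grid. Each perturbation is built to degrade
exactly one thing: `flatten_chiral` projects a stereocenter into its
neighbor plane (sp², −1 stereocenter); `invert_parity` reflects a terminal
substituent into the implicit-H slot (the anomer flip — handedness only);
`change_bond_order` retargets one bond to the other order's reference
length; `delete_atom` forces the subgraph fallback; `rename_atoms` and
`relabel_id` test nomenclature and status logic; `link_to_polymer` removes
the flagged leaving atom and plants an asparagine-like polymer residue with
its side-chain nitrogen at the vacated position.

**What passing these fixtures does not show.** Real experimental ligands
have refined, strained geometries: amide C–N bonds near 1.33 Å (which the
nearest-reference classifier would call double), thermal noise far above
0.02 Å, partial occupancies, genuinely missing atoms and protonation
ambiguity. The fixtures establish the correctness of the graph machinery,
the score algebra and the decomposition logic under unambiguous geometry —
not the robustness of bond-order perception against crystallographic
reality, which production systems delegate to dedicated perception engines.

## Scale and determinism

The toy dictionary (15 definitions, ≤ 28 heavy atoms each) and entries of
up to ~20 instances keep the whole test suite and the acceptance script in
the seconds range. Isomorphism enumeration is capped at 2000 mappings per
candidate — far above what any fixture's automorphism group produces. All
randomness (coordinate jitter) flows from a single seed; dictionaries,
entries, reports and file serializations are byte-deterministic, and the
pipeline is idempotent on its own output.

## Known limitations

* Formal charges are taken as stated, never perceived from geometry.
* No kekulization or tautomer handling; aromatic bonds compare as the
  single label "aromatic".
* Alternate conformers: only the highest-occupancy alt-loc (ties:
  alphabetically first) is perceived and matched.
* The subgraph fallback scores missing atoms against the full definition
  but does not attempt fuzzy matching across different element counts, nor
  fingerprint-based similarity search.
* Idealized coordinates of edited definitions are approximate; full 3D
  re-embedding is out of scope.
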