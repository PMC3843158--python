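"""Reading and writing component definitions and structure entries.

Definitions use the PDBx/mmCIF ``chem_comp`` dialect (the ``chem_comp``,
``chem_comp_atom`` and ``chem_comp_bond`` categories with the field names of
the public component dictionary); unrecognized categories are ignored so real
dictionary files remain readable. Structure entries are read and written in
mmCIF or PDB format. All parsing and serialization goes through gemmi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi

from ._chem import COVALENT_RADII

__all__ = [
    "AtomDef", "BondDef", "ComponentDefinition",
    "EntryAtom", "Residue", "StructureEntry", "Dictionary",
    "read_dictionary", "write_dictionary", "read_entry", "write_entry",
]

BOND_ORDERS = ("single", "double", "triple")
_ORDER_TO_CIF = {"single": "SING", "double": "DOUB", "triple": "TRIP"}
_CIF_TO_ORDER = {v: k for k, v in _ORDER_TO_CIF.items()}


@dataclass(frozen=True)
class AtomDef:
    """One atom of a component definition, with idealized coordinates."""

    name: str
    element: str
    charge: int = 0
    aromatic: bool = False
    stereo: str = "none"          # "R", "S" or "none": stereocenter marker
    xyz: tuple[float, float, float] = (0.0, 0.0, 0.0)
    leaving: bool = False


@dataclass(frozen=True)
class BondDef:
    atom1: str
    atom2: str
    order: str = "single"         # single | double | triple
    aromatic: bool = False


@dataclass
class ComponentDefinition:
    """A dictionary entry: named atoms, bonds with orders, ideal geometry."""

    comp_id: str
    name: str = ""
    formula: str = ""
    atoms: list[AtomDef] = field(default_factory=list)
    bonds: list[BondDef] = field(default_factory=list)

    def validate(self) -> None:
        if not (1 <= len(self.comp_id) <= 3 and self.comp_id.isalnum()):
            raise ValueError(f"invalid comp_id {self.comp_id!r}")
        if self.comp_id != self.comp_id.upper():
            raise ValueError(f"comp_id {self.comp_id!r} must be uppercase")
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.comp_id}: duplicate atom names")
        known = set(names)
        for b in self.bonds:
            if b.atom1 == b.atom2:
                raise ValueError(f"{self.comp_id}: self-bond on {b.atom1}")
            for end in (b.atom1, b.atom2):
                if end not in known:
                    raise ValueError(
                        f"{self.comp_id}: bond {b.atom1}-{b.atom2} names "
                        f"missing atom {end!r}")
            if b.order not in BOND_ORDERS:
                raise ValueError(f"{self.comp_id}: bad order {b.order!r}")
        for a in self.atoms:
            if a.element.upper() not in COVALENT_RADII:
                raise ValueError(
                    f"{self.comp_id}: unknown element {a.element!r}")
            if a.stereo not in ("R", "S", "none"):
                raise ValueError(f"{self.comp_id}: bad stereo {a.stereo!r}")

    def atom(self, name: str) -> AtomDef:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.comp_id}: no atom {name!r}")

    def heavy_atoms(self) -> list[AtomDef]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    def element_counts(self) -> tuple[tuple[str, int], ...]:
        """Sorted heavy-atom (element, count) vector — the prescreen key."""
        counts: dict[str, int] = {}
        for a in self.heavy_atoms():
            e = a.element.capitalize()
            counts[e] = counts.get(e, 0) + 1
        return tuple(sorted(counts.items()))


@dataclass(frozen=True)
class EntryAtom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str = ""
    comp_id: str = ""
    atoms: list[EntryAtom] = field(default_factory=list)
    polymer: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)


@dataclass
class StructureEntry:
    entry_id: str = "XXXX"
    residues: list[Residue] = field(default_factory=list)
    # ordered subcomponent ids for large ligands, keyed by residue key
    subcomponents: dict[tuple[str, int, str], list[str]] = field(
        default_factory=dict)

    def validate(self) -> None:
        if not any(r.atoms for r in self.residues):
            raise ValueError("no atoms in entry")
        seen: set[tuple] = set()
        for r in self.residues:
            for a in r.atoms:
                if a.element.upper() != "H" and a.element.upper() not in COVALENT_RADII:
                    raise ValueError(
                        f"{r.chain}/{r.seqnum} {a.name}: unknown element "
                        f"{a.element!r}")
                if not all(math.isfinite(c) for c in a.xyz):
                    raise ValueError(
                        f"{r.chain}/{r.seqnum} {a.name}: non-finite coords")
                k = (r.chain, r.seqnum, r.icode, a.altloc, a.name)
                if k in seen:
                    raise ValueError(f"duplicate atom {k}")
                seen.add(k)

    def residue(self, chain: str, seqnum: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain, seqnum, icode):
                return r
        raise KeyError(f"no residue {chain}/{seqnum}{icode}")


class Dictionary:
    """In-memory component dictionary with a heavy-element-count prescreen
    index kept consistent across inserts and removals."""

    def __init__(self, components: list[ComponentDefinition] | None = None):
        self._components: dict[str, ComponentDefinition] = {}
        self._index: dict[tuple, set[str]] = {}
        self._graph_cache: dict[str, object] = {}  # perceived graphs
        for c in components or []:
            self.add(c)

    def __len__(self) -> int:
        return len(self._components)

    def __contains__(self, comp_id: str) -> bool:
        return comp_id in self._components

    def __iter__(self):
        return iter(sorted(self._components))

    def __getitem__(self, comp_id: str) -> ComponentDefinition:
        return self._components[comp_id]

    def add(self, comp: ComponentDefinition) -> None:
        comp.validate()
        if comp.comp_id in self._components:
            raise ValueError(f"duplicate comp_id {comp.comp_id}")
        self._components[comp.comp_id] = comp
        self._index.setdefault(comp.element_counts(), set()).add(comp.comp_id)
        self._graph_cache.pop(comp.comp_id, None)

    def remove(self, comp_id: str) -> None:
        comp = self._components.pop(comp_id)
        key = comp.element_counts()
        self._index[key].discard(comp_id)
        if not self._index[key]:
            del self._index[key]
        self._graph_cache.pop(comp_id, None)

    def by_element_counts(self, key: tuple) -> list[str]:
        """comp_ids whose heavy-atom element-count vector equals ``key``."""
        return sorted(self._index.get(tuple(key), ()))

    def ids(self) -> list[str]:
        return sorted(self._components)


# ---------------------------------------------------------------------------
# chem_comp dictionary files

def _parse_block(block: "gemmi.cif.Block") -> ComponentDefinition:
    comp_id = block.find_value("_chem_comp.id") or block.name
    comp_id = gemmi.cif.as_string(comp_id)
    name = block.find_value("_chem_comp.name") or ""
    formula = block.find_value("_chem_comp.formula") or ""
    comp = ComponentDefinition(
        comp_id=comp_id,
        name=gemmi.cif.as_string(name),
        formula=gemmi.cif.as_string(formula),
    )
    atab = block.find("_chem_comp_atom.", [
        "atom_id", "type_symbol", "charge",
        "pdbx_aromatic_flag", "pdbx_stereo_config", "pdbx_leaving_atom_flag",
        "model_Cartn_x_ideal", "model_Cartn_y_ideal", "model_Cartn_z_ideal",
    ])
    for row in atab:
        stereo = gemmi.cif.as_string(row[4]).upper()
        comp.atoms.append(AtomDef(
            name=gemmi.cif.as_string(row[0]),
            element=gemmi.cif.as_string(row[1]).capitalize(),
            charge=int(gemmi.cif.as_int(row[2], 0)),
            aromatic=gemmi.cif.as_string(row[3]).upper() == "Y",
            stereo=stereo if stereo in ("R", "S") else "none",
            xyz=(gemmi.cif.as_number(row[6], 0.0),
                 gemmi.cif.as_number(row[7], 0.0),
                 gemmi.cif.as_number(row[8], 0.0)),
            leaving=gemmi.cif.as_string(row[5]).upper() == "Y",
        ))
    btab = block.find("_chem_comp_bond.", [
        "atom_id_1", "atom_id_2", "value_order", "pdbx_aromatic_flag",
    ])
    for row in btab:
        order = gemmi.cif.as_string(row[2]).upper()
        comp.bonds.append(BondDef(
            atom1=gemmi.cif.as_string(row[0]),
            atom2=gemmi.cif.as_string(row[1]),
            order=_CIF_TO_ORDER.get(order, "single"),
            aromatic=gemmi.cif.as_string(row[3]).upper() == "Y",
        ))
    try:
        comp.validate()
    except ValueError as exc:
        raise ValueError(f"block {block.name}: {exc}") from exc
    return comp


def read_dictionary(path) -> Dictionary:
    """Read a component dictionary from a (possibly concatenated) mmCIF file."""
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    d = Dictionary()
    for block in doc:
        if not block.find_values("_chem_comp_atom.atom_id") and \
                not block.find_value("_chem_comp.id"):
            continue  # not a component block
        d.add(_parse_block(block))
    return d


def write_dictionary(d: Dictionary, path) -> None:
    """Serialize deterministically: components sorted by id, atoms in stored
    order; two writes of equal dictionaries are byte-identical."""
    doc = gemmi.cif.Document()
    for comp_id in d.ids():
        comp = d[comp_id]
        block = doc.add_new_block(comp_id)
        block.set_pair("_chem_comp.id", comp_id)
        block.set_pair("_chem_comp.name", gemmi.cif.quote(comp.name or "?"))
        block.set_pair("_chem_comp.formula",
                       gemmi.cif.quote(comp.formula or "?"))
        if comp.atoms:
            loop = block.init_loop("_chem_comp_atom.", [
                "comp_id", "atom_id", "type_symbol", "charge",
                "pdbx_aromatic_flag", "pdbx_stereo_config",
                "pdbx_leaving_atom_flag",
                "model_Cartn_x_ideal", "model_Cartn_y_ideal",
                "model_Cartn_z_ideal",
            ])
            for a in comp.atoms:
                loop.add_row([
                    comp_id, gemmi.cif.quote(a.name), a.element.upper(),
                    str(a.charge), "Y" if a.aromatic else "N",
                    a.stereo if a.stereo != "none" else "N",
                    "Y" if a.leaving else "N",
                    f"{a.xyz[0]:.3f}", f"{a.xyz[1]:.3f}", f"{a.xyz[2]:.3f}",
                ])
        if comp.bonds:
            loop = block.init_loop("_chem_comp_bond.", [
                "comp_id", "atom_id_1", "atom_id_2", "value_order",
                "pdbx_aromatic_flag",
            ])
            for b in comp.bonds:
                loop.add_row([
                    comp_id, gemmi.cif.quote(b.atom1), gemmi.cif.quote(b.atom2),
                    _ORDER_TO_CIF[b.order], "Y" if b.aromatic else "N",
                ])
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# structure entries

def _entry_from_gemmi(st: gemmi.Structure) -> StructureEntry:
    entry = StructureEntry(entry_id=st.name or "XXXX")
    for model in st:
        for chain in model:
            for res in chain:
                residue = Residue(
                    chain=chain.name,
                    seqnum=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    comp_id=res.name,
                    polymer=(res.het_flag == "A"),
                )
                for atom in res:
                    residue.atoms.append(EntryAtom(
                        name=atom.name,
                        element=atom.element.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                        altloc=atom.altloc if atom.altloc != "\0" else "",
                    ))
                entry.residues.append(residue)
        break  # first model only
    entry.validate()
    return entry


def read_entry(path, format: str = "auto") -> StructureEntry:
    """Read a structure entry in mmCIF or PDB format."""
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    return _entry_from_gemmi(st)


def _entry_to_gemmi(entry: StructureEntry) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = entry.entry_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in entry.residues:
        if r.chain not in chains:
            chains[r.chain] = gemmi.Chain(r.chain)
        res = gemmi.Residue()
        res.name = r.comp_id
        res.seqid = gemmi.SeqId(r.seqnum, r.icode or " ")
        res.het_flag = "A" if r.polymer else "H"
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.xyz)
            atom.occ = a.occupancy
            atom.altloc = a.altloc or "\0"
            res.add_atom(atom)
        chains[r.chain].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_entry(entry: StructureEntry, path, format: str = "pdb") -> None:
    entry.validate()
    st = _entry_to_gemmi(entry)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
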