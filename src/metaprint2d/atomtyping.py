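"""Sybyl (Tripos forcefield) atom typing.

Every atom of a perceived molecule is assigned exactly one type from a fixed
33-member table combining element, hybridisation and aromaticity (e.g. ``C.ar``
for aromatic carbon, ``N.am`` for amide nitrogen).  The table order is frozen
because type ordinals are serialised into fingerprint databases; database build
and prediction must therefore share one table.

Hydrogens are explicit, typed atoms: ``H`` is a table member and circular
environments count hydrogen shells like any other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .errors import TypeLookupError, TypingError

#: Frozen Sybyl type table.  Ordinals are serialised; never reorder.
SYBYL_TYPES: tuple[str, ...] = (
    "C.3", "C.2", "C.ar", "C.1", "N.3", "N.2", "N.1", "O.3", "O.2", "S.3",
    "N.ar", "P.3", "H", "Br", "Cl", "F", "I", "S.2", "N.pl3", "LP",
    "Na", "K", "Ca", "Li", "Al", "Du", "Si", "N.am", "S.O", "S.O2",
    "N.4", "O.CO2", "C.cat",
)

_TYPE_TO_INDEX: dict[str, int] = {name: i for i, name in enumerate(SYBYL_TYPES)}

# Elements whose Sybyl type is just the element symbol.
_ELEMENT_TYPES = frozenset({"Br", "Cl", "F", "I", "Na", "K", "Ca", "Li", "Al", "Si"})


def type_index(name: str) -> int:
    """Return the fixed ordinal of a Sybyl type name (``"C.3"`` -> 0)."""
    try:
        return _TYPE_TO_INDEX[name]
    except KeyError:
        raise TypeLookupError(f"unknown Sybyl type name: {name!r}") from None


def type_name(index: int) -> str:
    """Inverse of :func:`type_index`."""
    if not 0 <= index < len(SYBYL_TYPES):
        raise TypeLookupError(f"Sybyl type index out of range: {index}")
    return SYBYL_TYPES[index]


@dataclass(frozen=True)
class AtomInfo:
    """One typed atom: element symbol, Sybyl type, aromatic flag, formal charge."""

    element: str
    sybyl_type: str
    aromatic: bool = False
    formal_charge: int = 0

    @property
    def type_index(self) -> int:
        return _TYPE_TO_INDEX[self.sybyl_type]


@dataclass
class TypedMolecule:
    """A molecule whose atoms carry Sybyl types.

    Atom indices are 0-based, contiguous and stable.  ``bonds`` holds
    ``(a, b, order)`` with order 1, 2, 3 or the string ``"ar"`` for aromatic
    bonds.  ``atom_map_numbers`` are per-atom positive integers (0 = unmapped)
    used to align reactant and product atoms across a transformation.
    """

    atoms: tuple[AtomInfo, ...]
    bonds: tuple[tuple[int, int, object], ...]
    atom_map_numbers: tuple[int, ...] = ()
    title: str = ""
    _adjacency: tuple | None = field(default=None, repr=False, compare=False)
    _env_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atom_map_numbers:
            self.atom_map_numbers = (0,) * len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> tuple[tuple[int, ...], ...]:
        """Neighbour lists, computed once on demand."""
        if self._adjacency is None:
            adj: list[list[int]] = [[] for _ in self.atoms]
            for a, b, _order in self.bonds:
                adj[a].append(b)
                adj[b].append(a)
            self._adjacency = tuple(tuple(n) for n in adj)
        return self._adjacency

    def type_indices(self) -> tuple[int, ...]:
        return tuple(a.type_index for a in self.atoms)

    def map_to_index(self) -> dict[int, int]:
        """Mapping atom-map number -> atom index for mapped atoms only."""
        return {m: i for i, m in enumerate(self.atom_map_numbers) if m > 0}


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}

# Functional-group patterns matched once per molecule before per-atom rules.
_PAT_CARBOXYLATE = Chem.MolFromSmarts("[CX3](=[OX1])[OX1-]")
_PAT_AMIDE_N = Chem.MolFromSmarts("[NX3][CX3]=[OX1,SX1]")
_PAT_GUANIDINIUM = Chem.MolFromSmarts(
    "[$([CX3](=[NX3+])([NX3])[NX3]),$([CX3+]([NX3])([NX3])[NX3])]"
)
_PAT_NITRO_N = Chem.MolFromSmarts("[$([NX3](=O)=O),$([NX3+](=O)[O-])]")


def _special_sets(mol: Chem.Mol) -> tuple[set[int], set[int], set[int], set[int]]:
    """Atom-index sets for carboxylate O, amide N, guanidinium C, nitro N."""
    o_co2: set[int] = set()
    for c, o_dbl, o_neg in mol.GetSubstructMatches(_PAT_CARBOXYLATE):
        o_co2.update((o_dbl, o_neg))
    # phosphate / phosphonate terminal oxygens share the O.CO2 type
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "P":
            for nbr in atom.GetNeighbors():
                if nbr.GetSymbol() == "O" and nbr.GetDegree() == 1:
                    o_co2.add(nbr.GetIdx())
    n_am = {m[0] for m in mol.GetSubstructMatches(_PAT_AMIDE_N)}
    c_cat = {m[0] for m in mol.GetSubstructMatches(_PAT_GUANIDINIUM)}
    n_no2 = {m[0] for m in mol.GetSubstructMatches(_PAT_NITRO_N)}
    return o_co2, n_am, c_cat, n_no2


def _has_double_bond(atom: Chem.Atom) -> bool:
    return any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds())


def _type_carbon(atom: Chem.Atom, c_cat: set[int]) -> str:
    if atom.GetIdx() in c_cat:
        return "C.cat"
    if atom.GetIsAromatic():
        return "C.ar"
    hyb = atom.GetHybridization()
    if hyb == Chem.HybridizationType.SP:
        return "C.1"
    if hyb == Chem.HybridizationType.SP2 or _has_double_bond(atom):
        return "C.2"
    return "C.3"


def _type_nitrogen(atom: Chem.Atom, n_am: set[int], n_no2: set[int]) -> str:
    idx = atom.GetIdx()
    if idx in n_am:
        return "N.am"
    if idx in n_no2:
        # nitro nitrogen: planar trigonal by convention
        return "N.pl3"
    if atom.GetIsAromatic():
        return "N.ar"
    if atom.GetTotalDegree() == 4 or (
        atom.GetFormalCharge() > 0 and not _has_double_bond(atom)
        and atom.GetHybridization() == Chem.HybridizationType.SP3
    ):
        return "N.4"
    hyb = atom.GetHybridization()
    if hyb == Chem.HybridizationType.SP:
        return "N.1"
    if _has_double_bond(atom):
        return "N.2"
    # three single bonds: planar if conjugated into an aromatic/sp2 system
    if atom.GetTotalDegree() == 3:
        for nbr in atom.GetNeighbors():
            if nbr.GetIsAromatic() or (
                nbr.GetSymbol() == "C"
                and nbr.GetHybridization() == Chem.HybridizationType.SP2
            ):
                return "N.pl3"
    return "N.3"


def _type_oxygen(atom: Chem.Atom, o_co2: set[int]) -> str:
    idx = atom.GetIdx()
    if idx in o_co2:
        return "O.CO2"
    if _has_double_bond(atom):
        return "O.2"
    if atom.GetFormalCharge() < 0 and atom.GetDegree() == 1:
        nbr = atom.GetNeighbors()[0].GetSymbol()
        if nbr in ("N", "S"):
            # nitro / N-oxide / sulfo charged oxygens behave like carbonyl O
            return "O.2"
    return "O.3"


def _type_sulfur(atom: Chem.Atom) -> str:
    n_oxo = sum(
        1
        for nbr in atom.GetNeighbors()
        if nbr.GetSymbol() == "O" and nbr.GetDegree() == 1
    )
    if n_oxo >= 2:
        return "S.O2"
    if n_oxo == 1 and atom.GetTotalDegree() >= 3:
        return "S.O"
    if _has_double_bond(atom):
        return "S.2"
    return "S.3"


def assign_sybyl_types(mol: Chem.Mol, title: str | None = None) -> TypedMolecule:
    """Type every atom of a sanitised RDKit molecule.

    Preconditions: the molecule is sanitised, aromaticity is perceived and
    hydrogens are explicit atoms (``Chem.AddHs``).  Elements outside the table
    map to ``Du`` (dummy).  Atom order is preserved.

    Raises
    ------
    TypingError
        If ``mol`` is None or carries a bond order outside {1, 2, 3, aromatic}.
    """
    if mol is None:
        raise TypingError("cannot type a missing molecule")
    o_co2, n_am, c_cat, n_no2 = _special_sets(mol)
    atoms: list[AtomInfo] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            t = "H"
        elif sym == "C":
            t = _type_carbon(atom, c_cat)
        elif sym == "N":
            t = _type_nitrogen(atom, n_am, n_no2)
        elif sym == "O":
            t = _type_oxygen(atom, o_co2)
        elif sym == "S":
            t = _type_sulfur(atom)
        elif sym == "P":
            t = "P.3"
        elif sym in _ELEMENT_TYPES:
            t = sym
        else:
            t = "Du"
        atoms.append(
            AtomInfo(
                element=sym,
                sybyl_type=t,
                aromatic=atom.GetIsAromatic(),
                formal_charge=atom.GetFormalCharge(),
            )
        )
    bonds: list[tuple[int, int, object]] = []
    for bond in mol.GetBonds():
        order = _BOND_ORDER.get(bond.GetBondType())
        if order is None:
            raise TypingError(
                f"unsupported bond order {bond.GetBondType()} between atoms "
                f"{bond.GetBeginAtomIdx()} and {bond.GetEndAtomIdx()}",
                atom_index=bond.GetBeginAtomIdx(),
            )
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    maps = tuple(a.GetAtomMapNum() for a in mol.GetAtoms())
    if title is None:
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return TypedMolecule(
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        atom_map_numbers=maps,
        title=title,
    )
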