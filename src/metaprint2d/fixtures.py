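"""Synthetic atom-mapped Phase I transformation corpora.

Curated metabolic-reaction databases are proprietary, so the rest of the
package is exercised against generated corpora instead: each record applies
one Phase I reaction class (aromatic/aliphatic hydroxylation, epoxidation,
O-/N-dealkylation, ester/amide hydrolysis) at a randomly chosen eligible site
of a randomly chosen drug-like scaffold, producing a chemically valid, fully
atom-mapped reactant/product pair.  A "poison" mix can inject Phase II-like
conjugations (glucuronidation, sulfation) which the database builder must
reject.

The true reaction-centre atoms ride alongside each record as ground truth —
in a sidecar table, never inside the record itself, so nothing under test can
see them.  Centres are recorded as atom-map numbers (map = reactant atom
index + 1), which survive SMILES round-trips where raw indices do not.

The corpus emulates the *machinery* of a curated transformation database —
mapped pairs, species tags, class mixture — not real metabolic
regioselectivity statistics.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .atomtyping import TypedMolecule, assign_sybyl_types
from .dbbuild import TransformationRecord
from .errors import FixtureError

#: Phase I classes and the Phase II "poison" classes the builder must reject.
PHASE1_CLASSES = (
    "aromatic_hydroxylation", "aliphatic_hydroxylation", "epoxidation",
    "o_dealkylation", "n_dealkylation", "ester_hydrolysis", "amide_hydrolysis",
)
POISON_CLASSES = ("glucuronidation", "sulfation")

#: Rough Phase I class frequencies for a drug-like corpus: CYP-mediated
#: hydroxylations dominate, dealkylations are common, epoxidations rare.
DEFAULT_REACTION_MIX: dict[str, float] = {
    "aromatic_hydroxylation": 0.25,
    "aliphatic_hydroxylation": 0.25,
    "epoxidation": 0.05,
    "o_dealkylation": 0.15,
    "n_dealkylation": 0.15,
    "ester_hydrolysis": 0.08,
    "amide_hydrolysis": 0.07,
}

DEFAULT_SPECIES_MIX: dict[str, float] = {"human": 0.5, "rat": 0.3, "dog": 0.2}


def default_scaffolds() -> tuple[str, ...]:
    """The hand-curated drug-like scaffold pool shipped with the package."""
    text = (importlib.resources.files("metaprint2d") / "data" / "scaffolds.smi").read_text()
    return tuple(line.split("\t")[0] for line in text.splitlines() if line.strip())


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus."""

    n_records: int = 100
    reaction_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REACTION_MIX))
    species_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIES_MIX))
    scaffold_pool: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise FixtureError("n_records must be >= 1")
        for name, mix in (("reaction_mix", self.reaction_mix),
                          ("species_mix", self.species_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise FixtureError(f"{name} proportions sum to {total}, not 1")
        known = set(PHASE1_CLASSES) | set(POISON_CLASSES)
        unknown = set(self.reaction_mix) - known
        if unknown:
            raise FixtureError(f"unknown reaction classes: {sorted(unknown)}")
        if not self.scaffold_pool:
            self.scaffold_pool = default_scaffolds()


@dataclass(frozen=True)
class GroundTruth:
    """Sidecar truth for one record: class, expected classification, centres."""

    record_id: str
    reaction_class: str
    expected_kind: str  # addition | elimination | rejected
    centre_maps: tuple[int, ...]  # atom-map numbers of true centres
    species: str

    def centre_indices(self, reactant: TypedMolecule) -> frozenset[int]:
        """Translate centre map numbers to indices on a parsed reactant."""
        m2i = reactant.map_to_index()
        return frozenset(m2i[m] for m in self.centre_maps)


# --- site matching -----------------------------------------------------------

_SITE_SMARTS = {
    "aromatic_hydroxylation": "[cH]",
    "aliphatic_hydroxylation": "[CX4;H1,H2,H3]",
    "epoxidation": "[CX3]=[CX3]",
    "o_dealkylation": "[#6;!$([CX3]=O)][OX2][CH3]",
    "n_dealkylation": "[NX3;!$([NX3]=O)][CH3]",
    "ester_hydrolysis": "[CX3](=[OX1])[OX2][#6]",
    "amide_hydrolysis": "[CX3](=[OX1])[NX3]",
    "glucuronidation": "[OX2H]",
    "sulfation": "[OX2H]",
}
_SITE_PATTERNS = {k: Chem.MolFromSmarts(v) for k, v in _SITE_SMARTS.items()}

_GLUCURONYL = Chem.MolFromSmiles("C1OC(C(=O)O)C(O)C(O)C1O")
_SULFO = Chem.MolFromSmiles("S(=O)(=O)O")

_SINGLE = Chem.BondType.SINGLE


def eligible_sites(mol: Chem.Mol, reaction_class: str) -> tuple[tuple[int, ...], ...]:
    """Substructure matches where ``reaction_class`` can apply."""
    return mol.GetSubstructMatches(_SITE_PATTERNS[reaction_class])


def _add_hydroxyl(rw: Chem.RWMol, centre: int) -> None:
    o = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(centre, o, _SINGLE)


def _delete_atoms(rw: Chem.RWMol, doomed: set[int]) -> None:
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)


def _drop_fragment_with(rw: Chem.RWMol, anchor: int) -> None:
    """Delete the connected fragment containing ``anchor`` (no-op if molecule
    is still connected, as when a lactone/lactam ring merely opens)."""
    frags = Chem.GetMolFrags(rw, sanitizeFrags=False)
    if len(frags) < 2:
        return
    for frag in frags:
        if anchor in frag:
            _delete_atoms(rw, set(frag))
            return


def _apply_reaction(mol: Chem.Mol, reaction_class: str, match: tuple[int, ...]) -> tuple[Chem.Mol, tuple[int, ...]]:
    """Apply one reaction at a matched site; returns (product, centre indices).

    Centre indices refer to the *reactant* numbering; added atoms are left
    unmapped so the diff sees them as new.
    """
    rw = Chem.RWMol(mol)
    if reaction_class in ("aromatic_hydroxylation", "aliphatic_hydroxylation"):
        (c,) = match[:1]
        _add_hydroxyl(rw, c)
        centres = (c,)
    elif reaction_class == "epoxidation":
        c1, c2 = match
        rw.GetBondBetweenAtoms(c1, c2).SetBondType(_SINGLE)
        o = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(c1, o, _SINGLE)
        rw.AddBond(c2, o, _SINGLE)
        centres = (c1, c2)
    elif reaction_class == "o_dealkylation":
        _attached, o, methyl = match
        rw.RemoveBond(o, methyl)
        _drop_fragment_with(rw, methyl)
        centres = (o, methyl)
    elif reaction_class == "n_dealkylation":
        n, methyl = match
        rw.RemoveBond(n, methyl)
        _drop_fragment_with(rw, methyl)
        centres = (n, methyl)
    elif reaction_class == "ester_hydrolysis":
        c_acyl, _o_dbl, o_ester, _c_alkyl = match
        rw.RemoveBond(c_acyl, o_ester)
        _drop_fragment_with(rw, o_ester)
        _add_hydroxyl(rw, _find_new_index(rw, mol, c_acyl))
        centres = (c_acyl, o_ester)
    elif reaction_class == "amide_hydrolysis":
        c_acyl, _o_dbl, n = match
        rw.RemoveBond(c_acyl, n)
        _drop_fragment_with(rw, n)
        _add_hydroxyl(rw, _find_new_index(rw, mol, c_acyl))
        centres = (c_acyl, n)
    elif reaction_class == "glucuronidation":
        (o,) = match
        anomeric = rw.GetNumAtoms()
        rw.InsertMol(_GLUCURONYL)
        rw.AddBond(o, anomeric, _SINGLE)
        centres = ()
    elif reaction_class == "sulfation":
        (o,) = match
        s = rw.GetNumAtoms()
        rw.InsertMol(_SULFO)
        rw.AddBond(o, s, _SINGLE)
        centres = ()
    else:
        raise FixtureError(f"unknown reaction class {reaction_class!r}")
    product = rw.GetMol()
    Chem.SanitizeMol(product)
    return product, centres


def _find_new_index(rw: Chem.RWMol, original: Chem.Mol, orig_idx: int) -> int:
    """Locate an original atom in an edited molecule via its map number."""
    target = original.GetAtomWithIdx(orig_idx).GetAtomMapNum()
    for atom in rw.GetAtoms():
        if atom.GetAtomMapNum() == target:
            return atom.GetIdx()
    raise FixtureError(f"atom with map {target} vanished during edit")


# --- corpus generation -------------------------------------------------------


class _ScaffoldCache:
    """Per-scaffold parsed/typed reactants and per-variant typed products.

    Corpora repeat (scaffold, class, site) combinations heavily; memoising the
    RDKit work keeps large corpora cheap and lets records share TypedMolecule
    objects (their environment caches then also amortise downstream).
    """

    def __init__(self, pool: tuple[str, ...]):
        self.mols: list[Chem.Mol] = []
        self.typed: list[TypedMolecule] = []
        for smi in pool:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise FixtureError(f"unparsable scaffold SMILES: {smi}")
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(atom.GetIdx() + 1)  # map = index + 1
            self.mols.append(mol)
            self.typed.append(assign_sybyl_types(Chem.AddHs(mol), title=smi))
        self.sites: dict[tuple[int, str], tuple] = {}
        self.products: dict[tuple[int, str, int], tuple[TypedMolecule, tuple[int, ...]]] = {}

    def eligible(self, scaffold: int, reaction_class: str):
        key = (scaffold, reaction_class)
        if key not in self.sites:
            self.sites[key] = eligible_sites(self.mols[scaffold], reaction_class)
        return self.sites[key]

    def product(self, scaffold: int, reaction_class: str, site: int):
        key = (scaffold, reaction_class, site)
        if key not in self.products:
            match = self.eligible(scaffold, reaction_class)[site]
            product, centres = _apply_reaction(self.mols[scaffold], reaction_class, match)
            typed = assign_sybyl_types(Chem.AddHs(product))
            self.products[key] = (typed, centres)
        return self.products[key]


_MAX_RESAMPLES = 50


def generate_corpus(spec: FixtureSpec) -> tuple[list[TransformationRecord], list[GroundTruth]]:
    """Generate a reproducible corpus and its sidecar ground truth.

    Each record draws a reaction class from ``reaction_mix``, a scaffold with
    at least one eligible site (bounded resampling, then an explicit scan over
    the pool; a class no scaffold supports raises :class:`FixtureError`), and
    a site uniformly among the eligible matches.  The same seed yields a
    byte-identical corpus.
    """
    rng = np.random.default_rng(spec.seed)
    cache = _ScaffoldCache(spec.scaffold_pool)
    classes = sorted(spec.reaction_mix)
    class_p = np.array([spec.reaction_mix[c] for c in classes])
    species = sorted(spec.species_mix)
    species_p = np.array([spec.species_mix[s] for s in species])
    n_scaffolds = len(spec.scaffold_pool)

    records: list[TransformationRecord] = []
    truths: list[GroundTruth] = []
    for i in range(spec.n_records):
        klass = classes[rng.choice(len(classes), p=class_p)]
        scaffold = None
        for _ in range(_MAX_RESAMPLES):
            cand = int(rng.integers(n_scaffolds))
            if cache.eligible(cand, klass):
                scaffold = cand
                break
        if scaffold is None:
            eligible = [s for s in range(n_scaffolds) if cache.eligible(s, klass)]
            if not eligible:
                raise FixtureError(f"no scaffold in the pool supports {klass}")
            scaffold = eligible[int(rng.integers(len(eligible)))]
        n_sites = len(cache.eligible(scaffold, klass))
        site = int(rng.integers(n_sites))
        product_typed, centres = cache.product(scaffold, klass, site)
        sp = species[rng.choice(len(species), p=species_p)]
        record_id = f"rec{i:05d}"
        records.append(TransformationRecord(
            reactant=cache.typed[scaffold],
            product=product_typed,
            species=sp,
            record_id=record_id,
        ))
        truths.append(GroundTruth(
            record_id=record_id,
            reaction_class=klass,
            expected_kind=(
                "rejected" if klass in POISON_CLASSES
                else "addition" if klass in (
                    "aromatic_hydroxylation", "aliphatic_hydroxylation", "epoxidation")
                else "elimination"
            ),
            centre_maps=tuple(sorted(c + 1 for c in centres)),
            species=sp,
        ))
    return records, truths


def extended_scaffolds() -> tuple[str, ...]:
    """A 50-molecule curated drug pool (superset of :func:`default_scaffolds`)."""
    text = (importlib.resources.files("metaprint2d") / "data" / "drugs_extended.smi").read_text()
    return tuple(line.split("\t")[0] for line in text.splitlines() if line.strip())


def expanded_scaffold_pool(n: int, seed: int = 0,
                           base: tuple[str, ...] | None = None) -> tuple[str, ...]:
    """``n`` distinct scaffolds, drawn from the curated pools first.

    Beyond the 50 curated drugs, extra molecules are derived by substituting
    one aromatic C-H of a base scaffold with F, Cl or methyl — enough
    chemical variety for tests that need many distinct reactants.
    """
    base = tuple(base) if base else extended_scaffolds()
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    for smi in base:
        canon = Chem.CanonSmiles(smi)
        if canon not in seen:
            seen.add(canon)
            out.append(smi)
    decorations = ("F", "Cl", "C")
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * n:
            raise FixtureError(f"could not derive {n} distinct scaffolds")
        mol = Chem.MolFromSmiles(base[int(rng.integers(len(base)))])
        sites = mol.GetSubstructMatches(_SITE_PATTERNS["aromatic_hydroxylation"])
        if not sites:
            continue
        (c,) = sites[int(rng.integers(len(sites)))]
        rw = Chem.RWMol(mol)
        new = rw.AddAtom(Chem.Atom(decorations[int(rng.integers(3))]))
        rw.AddBond(c, new, _SINGLE)
        try:
            product = rw.GetMol()
            Chem.SanitizeMol(product)
        except Exception:
            continue
        canon = Chem.MolToSmiles(product)
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    return tuple(out[:n])


def generate_single_centre_set(k: int, seed: int = 0) -> tuple[list[TransformationRecord], list[GroundTruth]]:
    """``k`` single-centre hydroxylation records on ``k`` distinct reactants.

    One record per reactant makes each record's centre the only atom of that
    molecule ever seen at a reaction centre, the setup for the self-recovery
    sanity check (query each reactant; its true centre should rank top).
    """
    pool = expanded_scaffold_pool(k, seed)
    rng = np.random.default_rng(seed)
    cache = _ScaffoldCache(pool)
    records: list[TransformationRecord] = []
    truths: list[GroundTruth] = []
    for i in range(k):
        eligible_classes = [
            c for c in ("aromatic_hydroxylation", "aliphatic_hydroxylation")
            if cache.eligible(i, c)
        ]
        if not eligible_classes:
            raise FixtureError(f"scaffold {pool[i]} has no hydroxylation site")
        klass = eligible_classes[int(rng.integers(len(eligible_classes)))]
        site = int(rng.integers(len(cache.eligible(i, klass))))
        product_typed, centres = cache.product(i, klass, site)
        record_id = f"sc{i:04d}"
        records.append(TransformationRecord(
            reactant=cache.typed[i], product=product_typed,
            species="human", record_id=record_id,
        ))
        truths.append(GroundTruth(
            record_id=record_id, reaction_class=klass, expected_kind="addition",
            centre_maps=tuple(sorted(c + 1 for c in centres)), species="human",
        ))
    return records, truths


def write_truth(truths: list[GroundTruth], path: str | Path) -> None:
    """Write the sidecar ground-truth TSV."""
    with open(path, "w") as fh:
        fh.write("record_id\treaction_class\texpected_kind\tcentre_maps\tspecies\n")
        for t in truths:
            fh.write(f"{t.record_id}\t{t.reaction_class}\t{t.expected_kind}\t"
                     f"{','.join(map(str, t.centre_maps))}\t{t.species}\n")


def read_truth(path: str | Path) -> list[GroundTruth]:
    """Read a sidecar ground-truth TSV."""
    out: list[GroundTruth] = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            rid, klass, kind, maps, sp = line.rstrip("\n").split("\t")
            out.append(GroundTruth(
                record_id=rid, reaction_class=klass, expected_kind=kind,
                centre_maps=tuple(int(m) for m in maps.split(",") if m),
                species=sp,
            ))
    return out
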