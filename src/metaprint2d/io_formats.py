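"""Reading and writing the chemistry formats the tool touches.

Structures come in as SMILES (one per line, optional tab-separated id), MDL
Molfile V2000 or SDF, via RDKit.  Batch predictions go out as SDF records
carrying per-atom results in three text properties, or as a flat TSV table.
Reaction files for database building are mapped reaction SMILES, one per
line, with optional species and record-id columns.

Readers stream lazily and skip unparsable records with a logged warning, so
one corrupt entry never aborts a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem

from .atomtyping import TypedMolecule, assign_sybyl_types
from .dbbuild import TransformationRecord
from .errors import ContractViolationError, ParseError
from .predict import AtomPrediction

logger = logging.getLogger(__name__)

#: SDF property names carrying batch prediction results.
PROP_NOR = "MetaPrint2D_NOR"
PROP_BANDS = "MetaPrint2D_Bands"
PROP_RC_OC = "MetaPrint2D_RC_OC"

_FORMATS = ("smiles", "molfile", "sdf")
_EXT_FORMAT = {
    ".smi": "smiles", ".smiles": "smiles", ".txt": "smiles",
    ".mol": "molfile", ".mdl": "molfile",
    ".sdf": "sdf", ".sd": "sdf",
}


@dataclass
class MoleculeRecord:
    """A typed structure plus its source properties and provenance."""

    structure: TypedMolecule
    properties: dict[str, str]
    source: tuple[str, int]  # (path, 0-based record index)
    mol: Chem.Mol = field(repr=False, compare=False, default=None)  # as read, pre-AddHs


def prepare(mol: Chem.Mol, title: str | None = None) -> TypedMolecule:
    """Add explicit hydrogens and assign Sybyl types to a sanitised mol."""
    return assign_sybyl_types(Chem.AddHs(mol), title=title)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ParseError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    inferred = _EXT_FORMAT.get(path.suffix.lower())
    if inferred is None:
        raise ParseError(f"cannot infer format from extension {path.suffix!r}; "
                         "pass format explicitly")
    return inferred


def read_molecules(path: str | Path, fmt: str | None = None) -> Iterator[MoleculeRecord]:
    """Lazily yield typed molecule records from a SMILES, Molfile or SDF file.

    Unparsable records are skipped with a warning naming their index; the
    stream never aborts mid-file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "smiles":
        yield from _read_smiles(path)
    elif fmt == "molfile":
        mol = Chem.MolFromMolFile(str(path), removeHs=False)
        if mol is None:
            logger.warning("skipping unparsable molfile record 0 in %s", path)
            return
        yield _record(mol, path, 0)
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unparsable SDF record %d in %s", i, path)
                continue
            yield _record(mol, path, i)


def _read_smiles(path: Path) -> Iterator[MoleculeRecord]:
    with open(path) as fh:
        index = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles, name = parts[0], (parts[1] if len(parts) > 1 else "")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                logger.warning("skipping unparsable SMILES record %d: %s", index, smiles)
                index += 1
                continue
            if name:
                mol.SetProp("_Name", name)
            yield _record(mol, path, index, title=name or smiles)
            index += 1


def _record(mol: Chem.Mol, path: Path, index: int, title: str | None = None) -> MoleculeRecord:
    props = {k: str(v) for k, v in mol.GetPropsAsDict().items()}
    return MoleculeRecord(
        structure=prepare(mol, title=title),
        properties=props,
        source=(str(path), index),
        mol=mol,
    )


def _fmt_nor(preds: list[AtomPrediction]) -> str:
    return ";".join(
        f"{p.atom_index}:{p.nor:.3f}" for p in preds if p.nor is not None
    )


def _fmt_bands(preds: list[AtomPrediction]) -> str:
    return ";".join(f"{p.atom_index}:{p.band}" for p in preds)


def _fmt_rc_oc(preds: list[AtomPrediction]) -> str:
    return ";".join(f"{p.atom_index}:{p.rc_sum}:{p.oc_sum}" for p in preds)


def write_predictions_sdf(
    results: Iterable[tuple[MoleculeRecord, list[AtomPrediction]]],
    path: str | Path,
) -> None:
    """Write records to SDF with predictions attached as text properties.

    Adds ``MetaPrint2D_NOR`` (``atom_index:nor`` semicolon list, 3 decimals),
    ``MetaPrint2D_Bands`` and ``MetaPrint2D_RC_OC`` (``atom_index:rc:oc``);
    original properties are preserved.  Atom indices refer to the typed
    molecule with explicit hydrogens (heavy atoms keep their input indices).
    """
    writer = Chem.SDWriter(str(path))
    try:
        for record, preds in results:
            if len(preds) != record.structure.n_atoms:
                raise ContractViolationError(
                    f"{len(preds)} predictions for {record.structure.n_atoms} atoms "
                    f"(record {record.source[1]} from {record.source[0]})"
                )
            mol = Chem.Mol(record.mol)
            for key, value in record.properties.items():
                mol.SetProp(key, value)
            mol.SetProp(PROP_NOR, _fmt_nor(preds))
            mol.SetProp(PROP_BANDS, _fmt_bands(preds))
            mol.SetProp(PROP_RC_OC, _fmt_rc_oc(preds))
            writer.write(mol)
    finally:
        writer.close()


def parse_nor_property(value: str) -> dict[int, float]:
    """Inverse of the ``MetaPrint2D_NOR`` formatting."""
    if not value.strip():
        return {}
    out = {}
    for chunk in value.split(";"):
        idx, nor = chunk.split(":")
        out[int(idx)] = float(nor)
    return out


def write_predictions_tsv(
    results: Iterable[tuple[MoleculeRecord, list[AtomPrediction]]],
    path: str | Path,
) -> None:
    """Flat per-atom table: one row per (molecule, atom)."""
    import pandas as pd

    rows = []
    for record, preds in results:
        mol_id = record.structure.title or f"record{record.source[1]}"
        for p in preds:
            rows.append({
                "molecule_id": mol_id,
                "atom_index": p.atom_index,
                "sybyl_type": record.structure.atoms[p.atom_index].sybyl_type,
                "rc_sum": p.rc_sum,
                "oc_sum": p.oc_sum,
                "ratio": "" if p.ratio is None else f"{p.ratio:.6f}",
                "nor": "" if p.nor is None else f"{p.nor:.3f}",
                "band": p.band,
            })
    pd.DataFrame(rows, columns=[
        "molecule_id", "atom_index", "sybyl_type", "rc_sum", "oc_sum",
        "ratio", "nor", "band",
    ]).to_csv(path, sep="\t", index=False)


def read_reactions(path: str | Path) -> Iterator[TransformationRecord]:
    """Read mapped reaction SMILES lines: ``reactant>>product[\\tspecies[\\tid]]``.

    Unparsable lines are skipped with a warning; atom-map numbers are
    preserved through parsing.
    """
    path = Path(path)
    with open(path) as fh:
        index = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rxn = parts[0]
            species = parts[1] if len(parts) > 1 else ""
            record_id = parts[2] if len(parts) > 2 else f"record{index}"
            try:
                reactant_smi, product_smi = rxn.split(">>")
            except ValueError:
                logger.warning("skipping malformed reaction line %d: %s", index, rxn)
                index += 1
                continue
            reactant = Chem.MolFromSmiles(reactant_smi)
            product = Chem.MolFromSmiles(product_smi)
            if reactant is None or product is None:
                logger.warning("skipping unparsable reaction record %d (%s)", index, record_id)
                index += 1
                continue
            yield TransformationRecord(
                reactant=prepare(reactant, title=record_id),
                product=prepare(product, title=record_id),
                species=species,
                record_id=record_id,
            )
            index += 1


def write_reactions(records: Iterable[TransformationRecord], path: str | Path) -> None:
    """Write transformation records as mapped reaction SMILES lines.

    Inverse of :func:`read_reactions` up to SMILES canonicalisation; the
    atom-map numbers carry the reactant/product correspondence.
    """
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{typed_to_smiles(rec.reactant)}>>{typed_to_smiles(rec.product)}"
                     f"\t{rec.species}\t{rec.record_id}\n")


def typed_to_smiles(mol: TypedMolecule) -> str:
    """Rebuild an RDKit mol from a typed molecule and emit mapped SMILES."""
    rw = Chem.RWMol()
    for info, map_num in zip(mol.atoms, mol.atom_map_numbers):
        atom = Chem.Atom(info.element)
        atom.SetFormalCharge(info.formal_charge)
        atom.SetAtomMapNum(map_num)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    bond_types = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                  3: Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}
    for a, b, order in mol.bonds:
        rw.AddBond(a, b, bond_types[order])
    built = rw.GetMol()
    Chem.SanitizeMol(built)
    return Chem.MolToSmiles(Chem.RemoveHs(built))
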