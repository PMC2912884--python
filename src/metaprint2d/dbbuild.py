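"""Build fingerprint-count databases from atom-mapped Phase I transformations.

A transformation record is a reactant/product pair sharing atom-map numbers.
Diffing the mapped graphs classifies each record:

* **addition** — the product is the reactant plus exactly one oxygen atom
  (hydroxylation, heteroatom oxidation, epoxidation); the reaction centre is
  every mapped atom bonded to the new oxygen.
* **elimination** — at least one reactant bond between mapped atoms is gone
  in the product (dealkylation, ester/amide hydrolysis); both endpoints of
  each broken bond are reaction centres.  Hydrolyses may add the single
  water-derived oxygen.
* **rejected** — anything else: bond-order-only changes (desaturations),
  multi-oxygen additions, and Phase II conjugations that graft whole
  fragments onto the substrate.

Every reactant atom of every record contributes one overall-occurrence (oc)
count for its depth-6 environment; reaction-centre atoms of accepted records
additionally contribute a reaction-centre (rc) count.  Identical environments
merge into a single record, so rc <= oc holds by construction.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atomtyping import SYBYL_TYPES, TypedMolecule
from .errors import CorruptionError, IncompatibilityError, MappingError, TruncationError
from .fingerprint import (
    DEFAULT_ALPHA,
    DEFAULT_DEPTH,
    DEFAULT_N_EXACT,
    AtomEnvironment,
    compute_all_environments,
    prefix_hash,
)

logger = logging.getLogger(__name__)

MAGIC = b"MP2D"
SENTINEL = 0xAB
_HEADER = struct.Struct(">IB")
_TAIL = struct.Struct(">iiB")
_MAX_BYTE = 0xFF
_MAX_INT32 = 0x7FFFFFFF


@dataclass
class TransformationRecord:
    """One atom-mapped biotransformation (reactant -> product)."""

    reactant: TypedMolecule
    product: TypedMolecule
    species: str = ""
    record_id: str = ""


@dataclass(frozen=True)
class ReactionCentreSet:
    """Classification of a transformation plus its reactant-side centres."""

    centres: frozenset[int]
    kind: str  # "addition" | "elimination" | "rejected"
    reject_reason: str = ""


@dataclass
class FingerprintRecord:
    """A unique environment with its reaction-centre and overall counts."""

    environment: AtomEnvironment
    rc: int
    oc: int


@dataclass
class MetabDatabase:
    """Hash-indexed collection of fingerprint records."""

    records: list[FingerprintRecord]
    n_levels: int = DEFAULT_DEPTH
    type_table: tuple[str, ...] = SYBYL_TYPES
    species_label: str = "all"
    build_report: pd.DataFrame | None = field(default=None, repr=False, compare=False)
    _indexes: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def hash_index(self, n_exact: int = DEFAULT_N_EXACT, alpha: int = DEFAULT_ALPHA) -> dict[int, list[int]]:
        """Map level-``n_exact``-prefix hash -> record indices (cached)."""
        key = (n_exact, alpha)
        index = self._indexes.get(key)
        if index is None:
            index = {}
            for i, rec in enumerate(self.records):
                index.setdefault(prefix_hash(rec.environment, n_exact, alpha), []).append(i)
            self._indexes[key] = index
        return index


def _mapped_bonds(mol: TypedMolecule) -> dict[tuple[int, int], object]:
    """Bonds between mapped atoms, keyed by sorted map-number pair."""
    maps = mol.atom_map_numbers
    out: dict[tuple[int, int], object] = {}
    for a, b, order in mol.bonds:
        ma, mb = maps[a], maps[b]
        if ma > 0 and mb > 0:
            out[(min(ma, mb), max(ma, mb))] = order
    return out


def _check_unique_maps(mol: TypedMolecule, side: str, record_id: str) -> None:
    seen: set[int] = set()
    for m in mol.atom_map_numbers:
        if m > 0:
            if m in seen:
                raise MappingError(f"duplicate atom-map number {m} on {side}", record_id)
            seen.add(m)


def diff_transformation(rec: TransformationRecord) -> ReactionCentreSet:
    """Diff the mapped reactant/product graphs and classify the record.

    A broken mapped-mapped bond takes precedence over the added-oxygen test:
    hydrolysis records whose products are concatenated fragments show one
    added (water) oxygen as well as the broken bond, and are eliminations.
    """
    _check_unique_maps(rec.reactant, "reactant", rec.record_id)
    _check_unique_maps(rec.product, "product", rec.record_id)
    r_map = rec.reactant.map_to_index()
    p_map = rec.product.map_to_index()
    if not r_map or not p_map or not (r_map.keys() & p_map.keys()):
        raise MappingError("no shared atom-map numbers between reactant and product",
                           rec.record_id)

    r_bonds = _mapped_bonds(rec.reactant)
    p_bonds = _mapped_bonds(rec.product)
    # A bond is broken if it is gone while at least one endpoint survives;
    # bonds wholly inside a departed fragment left intact with it.
    broken = [
        pair for pair in r_bonds
        if pair not in p_bonds and (pair[0] in p_map or pair[1] in p_map)
    ]
    order_changed = [
        pair for pair, order in r_bonds.items()
        if pair in p_bonds and p_bonds[pair] != order
    ]
    added_heavy = [
        i for i, m in enumerate(rec.product.atom_map_numbers)
        if rec.product.atoms[i].element != "H" and (m == 0 or m not in r_map)
    ]
    lost = [m for m in r_map if m not in p_map]

    def centre_indices(map_pairs) -> frozenset[int]:
        out = set()
        for pair in map_pairs:
            for m in pair:
                out.add(r_map[m])
        return frozenset(out)

    if broken:
        added_ok = not added_heavy or (
            len(added_heavy) == 1
            and rec.product.atoms[added_heavy[0]].element == "O"
        )
        if added_ok:
            return ReactionCentreSet(centres=centre_indices(broken), kind="elimination")
        return ReactionCentreSet(
            centres=frozenset(), kind="rejected",
            reject_reason="bond cleavage combined with non-water addition",
        )
    if len(added_heavy) == 1 and rec.product.atoms[added_heavy[0]].element == "O":
        new_o = added_heavy[0]
        p_maps = rec.product.atom_map_numbers
        adj = rec.product.adjacency()
        centres = frozenset(
            r_map[p_maps[nbr]]
            for nbr in adj[new_o]
            if p_maps[nbr] in r_map
        )
        if centres:
            return ReactionCentreSet(centres=centres, kind="addition")
        return ReactionCentreSet(
            centres=frozenset(), kind="rejected",
            reject_reason="added oxygen not bonded to any mapped atom",
        )
    if added_heavy:
        return ReactionCentreSet(
            centres=frozenset(), kind="rejected",
            reject_reason=f"addition of {len(added_heavy)} heavy atoms "
                          "(not a single oxygen; Phase II-like)",
        )
    if lost:
        return ReactionCentreSet(
            centres=frozenset(), kind="rejected",
            reject_reason="atoms lost without a broken mapped bond",
        )
    if order_changed:
        return ReactionCentreSet(
            centres=frozenset(), kind="rejected",
            reject_reason="bond-order change only",
        )
    return ReactionCentreSet(
        centres=frozenset(), kind="rejected", reject_reason="no structural change",
    )


def build_database(
    records: list[TransformationRecord],
    species_filter: str | None = None,
    depth: int = DEFAULT_DEPTH,
    count_all_reactants: bool = True,
) -> MetabDatabase:
    """Accumulate fingerprint counts over a set of transformation records.

    Every atom of every contributing reactant increments its environment's
    ``oc``; reaction-centre atoms of accepted records increment ``rc``.
    ``species_filter`` (None or ``"all"`` = no filter) restricts which records
    contribute.  With ``count_all_reactants=False`` only accepted (addition or
    elimination) records contribute overall counts.

    The returned database carries a per-record build report
    (record_id, kind, centres, reject_reason) as a DataFrame.
    """
    counts: dict[tuple, list[int]] = {}
    envs_by_key: dict[tuple, AtomEnvironment] = {}
    report_rows = []
    n_kind = {"addition": 0, "elimination": 0, "rejected": 0}
    for rec in records:
        if species_filter not in (None, "", "all") and rec.species != species_filter:
            continue
        rcs = diff_transformation(rec)
        n_kind[rcs.kind] += 1
        report_rows.append({
            "record_id": rec.record_id,
            "kind": rcs.kind,
            "centres": ",".join(str(i) for i in sorted(rcs.centres)),
            "reject_reason": rcs.reject_reason,
        })
        accepted = rcs.kind != "rejected"
        if not accepted and not count_all_reactants:
            continue
        envs = compute_all_environments(rec.reactant, depth)
        for i, env in enumerate(envs):
            entry = counts.get(env.levels)
            if entry is None:
                entry = counts[env.levels] = [0, 0]
                envs_by_key[env.levels] = AtomEnvironment(-1, env.levels)
            entry[1] += 1
            if accepted and i in rcs.centres:
                entry[0] += 1
    if n_kind["addition"] + n_kind["elimination"] == 0:
        warnings.warn("no accepted Phase I records; database has rc=0 everywhere",
                      stacklevel=2)
    logger.info(
        "built database: %d additions, %d eliminations, %d rejected, %d unique environments",
        n_kind["addition"], n_kind["elimination"], n_kind["rejected"], len(counts),
    )
    db_records = [
        FingerprintRecord(environment=envs_by_key[key], rc=rc, oc=oc)
        for key, (rc, oc) in counts.items()
    ]
    return MetabDatabase(
        records=db_records,
        n_levels=depth,
        species_label=species_filter or "all",
        build_report=pd.DataFrame(
            report_rows, columns=["record_id", "kind", "centres", "reject_reason"]
        ),
    )


def merge_databases(a: MetabDatabase, b: MetabDatabase) -> MetabDatabase:
    """Sum the count tables of two databases built with identical settings.

    Building from a union of record sets equals merging the databases built
    from the parts (additivity).
    """
    if a.n_levels != b.n_levels or a.type_table != b.type_table:
        raise IncompatibilityError("cannot merge databases with differing depth or type table")
    counts: dict[tuple, list[int]] = {}
    for db in (a, b):
        for rec in db.records:
            entry = counts.setdefault(rec.environment.levels, [0, 0])
            entry[0] += rec.rc
            entry[1] += rec.oc
    merged = [
        FingerprintRecord(AtomEnvironment(-1, key), rc, oc)
        for key, (rc, oc) in counts.items()
    ]
    label = a.species_label if a.species_label == b.species_label else "merged"
    return MetabDatabase(records=merged, n_levels=a.n_levels,
                         type_table=a.type_table, species_label=label)


def _clamp_byte(value: int, what: str) -> int:
    if value > _MAX_BYTE:
        warnings.warn(f"{what} {value} exceeds one byte; clamped to 255", stacklevel=3)
        return _MAX_BYTE
    return value


def write_db(db: MetabDatabase, path: str | Path) -> None:
    """Serialise a database to the sparse big-endian binary layout.

    Layout: magic ``MP2D``; u32 record count; u8 number of levels; then per
    record: for each level a u8 non-zero-entry count followed by (u8 type
    index, u8 count) pairs; i32 rc; i32 oc; and a fixed sentinel byte 0xAB
    for corruption detection.  Counts wider than a byte clamp with a warning.
    Species labels and other metadata are not part of the layout.
    """
    buf = bytearray(MAGIC)
    buf += _HEADER.pack(len(db.records), db.n_levels)
    for rec in db.records:
        for level in rec.environment.levels:
            buf.append(len(level))
            for idx, count in level:
                buf.append(idx)
                buf.append(_clamp_byte(count, "type count"))
        buf += _TAIL.pack(min(rec.rc, _MAX_INT32), min(rec.oc, _MAX_INT32), SENTINEL)
    Path(path).write_bytes(bytes(buf))


def db_nbytes(db: MetabDatabase) -> int:
    """Closed-form size in bytes of ``write_db`` output."""
    n = len(MAGIC) + _HEADER.size
    for rec in db.records:
        n += sum(1 + 2 * len(level) for level in rec.environment.levels)
        n += _TAIL.size
    return n


def read_db(path: str | Path) -> MetabDatabase:
    """Read a serialised database; the hash index is rebuilt lazily on use.

    Raises :class:`CorruptionError` (with byte offset and record index) on a
    bad magic or sentinel byte, :class:`TruncationError` if the file ends
    before its declared content.
    """
    data = Path(path).read_bytes()
    if data[:4] != MAGIC:
        raise CorruptionError(f"bad magic {data[:4]!r} at byte 0", offset=0)
    if len(data) < 4 + _HEADER.size:
        raise TruncationError("file ends inside header", offset=len(data))
    n_records, n_levels = _HEADER.unpack_from(data, 4)
    off = 4 + _HEADER.size
    records: list[FingerprintRecord] = []
    for k in range(n_records):
        levels: list[tuple[tuple[int, int], ...]] = []
        for _ in range(n_levels):
            if off >= len(data):
                raise TruncationError(f"file ends inside record {k}", offset=off,
                                      record_index=k)
            nnz = data[off]
            off += 1
            if off + 2 * nnz > len(data):
                raise TruncationError(f"file ends inside record {k}", offset=off,
                                      record_index=k)
            level = tuple(
                (data[off + 2 * j], data[off + 2 * j + 1]) for j in range(nnz)
            )
            off += 2 * nnz
            levels.append(level)
        if off + _TAIL.size > len(data):
            raise TruncationError(f"file ends inside record {k}", offset=off,
                                  record_index=k)
        rc, oc, sentinel = _TAIL.unpack_from(data, off)
        off += _TAIL.size
        if sentinel != SENTINEL:
            raise CorruptionError(
                f"record {k}: bad sentinel byte 0x{sentinel:02X} at byte {off - 1}",
                offset=off - 1, record_index=k,
            )
        records.append(FingerprintRecord(AtomEnvironment(-1, tuple(levels)), rc, oc))
    return MetabDatabase(records=records, n_levels=n_levels, species_label="")


def write_build_report(db: MetabDatabase, path: str | Path) -> None:
    """Write the per-record classification report as TSV."""
    if db.build_report is None:
        raise ValueError("database carries no build report")
    db.build_report.to_csv(path, sep="\t", index=False)
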