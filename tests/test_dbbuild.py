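"""Transformation diffing, count bookkeeping, merging, binary round-trips."""

import pytest
from rdkit import Chem

import metaprint2d as mp
from metaprint2d.dbbuild import SENTINEL, db_nbytes
from metaprint2d.errors import CorruptionError, MappingError, TruncationError
from metaprint2d.fingerprint import AtomEnvironment

from conftest import make_reaction

TOLUENE = "[CH3:7][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"
BENZYL_ALCOHOL = "O[CH2:7][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"
ANISOLE = "[CH3:8][O:7][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"
PHENOL = "[OH:7][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"
BENZOIC_ACID = "OC(=O)[c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1"


def test_benzylic_hydroxylation_is_addition():
    rec = make_reaction(TOLUENE, BENZYL_ALCOHOL)
    rcs = mp.diff_transformation(rec)
    assert rcs.kind == "addition"
    assert rcs.centres == {rec.reactant.map_to_index()[7]}  # the benzylic carbon


def test_o_demethylation_is_elimination_with_both_endpoints():
    rec = make_reaction(ANISOLE, PHENOL)
    rcs = mp.diff_transformation(rec)
    m2i = rec.reactant.map_to_index()
    assert rcs.kind == "elimination"
    assert rcs.centres == {m2i[7], m2i[8]}  # ether O and methyl C


def test_double_oxidation_rejected():
    rcs = mp.diff_transformation(make_reaction(TOLUENE, BENZOIC_ACID))
    assert rcs.kind == "rejected"


def test_desaturation_rejected_as_bond_order_only():
    rcs = mp.diff_transformation(make_reaction("[CH3:1][CH3:2]", "[CH2:1]=[CH2:2]"))
    assert rcs.kind == "rejected"
    assert "bond-order" in rcs.reject_reason


def test_duplicate_map_numbers_raise():
    rec = make_reaction("[CH3:1][CH3:1]", "[CH3:1][CH2:2]O", record_id="dup")
    with pytest.raises(MappingError, match="dup"):
        mp.diff_transformation(rec)


def test_no_shared_maps_raise():
    rec = make_reaction("[CH4:1]", "[CH4:2]")
    with pytest.raises(MappingError):
        mp.diff_transformation(rec)


def diff_oracle(rec: mp.TransformationRecord):
    """Independent reaction-centre derivation from mapped bond-list set diffs."""

    def mapped_bonds(tm):
        maps = tm.atom_map_numbers
        return {frozenset((maps[a], maps[b]))
                for a, b, _ in tm.bonds if maps[a] > 0 and maps[b] > 0}

    r_bonds = mapped_bonds(rec.reactant)
    p_bonds = mapped_bonds(rec.product)
    p_present = {m for m in rec.product.atom_map_numbers if m > 0}
    m2i = rec.reactant.map_to_index()
    broken = {bond for bond in r_bonds - p_bonds if bond & p_present}
    if broken:
        return {m2i[m] for bond in broken for m in bond}
    # addition: centre = mapped neighbours of the unmapped heavy atom
    adj = rec.product.adjacency()
    centres = set()
    for i, m in enumerate(rec.product.atom_map_numbers):
        if m == 0 and rec.product.atoms[i].element == "O":
            for nbr in adj[i]:
                mn = rec.product.atom_map_numbers[nbr]
                if mn in m2i:
                    centres.add(m2i[mn])
    return centres


def test_centres_match_independent_bond_diff_oracle(corpus):
    records, truths = corpus
    for rec, truth in zip(records, truths):
        rcs = mp.diff_transformation(rec)
        if truth.expected_kind == "rejected":
            assert rcs.kind == "rejected"
        else:
            assert rcs.centres == diff_oracle(rec), rec.record_id


def test_single_record_bookkeeping():
    rec = make_reaction(TOLUENE, BENZYL_ALCOHOL)
    db = mp.build_database([rec])
    centre = rec.reactant.map_to_index()[7]
    centre_env = mp.compute_environment(rec.reactant, centre)
    by_levels = {r.environment.levels: r for r in db.records}
    assert by_levels[centre_env.levels].rc == 1
    assert all(r.oc >= 1 for r in db.records)
    assert sum(r.oc for r in db.records) == rec.reactant.n_atoms


def test_duplicate_record_doubles_all_counts():
    rec = make_reaction(TOLUENE, BENZYL_ALCOHOL)
    single = {r.environment.levels: (r.rc, r.oc) for r in mp.build_database([rec]).records}
    double = {r.environment.levels: (r.rc, r.oc) for r in mp.build_database([rec, rec]).records}
    assert double == {k: (rc * 2, oc * 2) for k, (rc, oc) in single.items()}


def test_rc_increment_conservation(corpus):
    records, _ = corpus
    db = mp.build_database(records)
    expected = sum(
        len(mp.diff_transformation(r).centres) for r in records
        if mp.diff_transformation(r).kind != "rejected"
    )
    assert sum(r.rc for r in db.records) == expected
    assert all(r.rc <= r.oc for r in db.records)


def counts_of(db):
    return {r.environment.levels: (r.rc, r.oc) for r in db.records}


def test_merge_equals_build_on_union(corpus):
    records, _ = corpus
    half = len(records) // 2
    merged = mp.merge_databases(
        mp.build_database(records[:half]), mp.build_database(records[half:])
    )
    assert counts_of(merged) == counts_of(mp.build_database(records))


def test_species_databases_sum_to_all(corpus):
    records, _ = corpus
    total = {}
    for species in ("human", "rat", "dog"):
        for key, (rc, oc) in counts_of(mp.build_database(records, species)).items():
            prc, poc = total.get(key, (0, 0))
            total[key] = (prc + rc, poc + oc)
    assert total == counts_of(mp.build_database(records, "all"))


def test_empty_accepted_set_warns_but_builds():
    rec = make_reaction("[CH3:1][CH3:2]", "[CH2:1]=[CH2:2]")
    with pytest.warns(UserWarning, match="no accepted"):
        db = mp.build_database([rec])
    assert len(db) > 0 and all(r.rc == 0 for r in db.records)


# --- serialisation -----------------------------------------------------------


def test_round_trip_identity(tmp_path, corpus_db):
    path = tmp_path / "db.bin"
    mp.write_db(corpus_db, path)
    assert path.stat().st_size == db_nbytes(corpus_db)
    back = mp.read_db(path)
    assert counts_of(back) == counts_of(corpus_db)
    assert [r.environment.levels for r in back.records] == \
           [r.environment.levels for r in corpus_db.records]


def test_bad_magic_detected(tmp_path, corpus_db):
    path = tmp_path / "db.bin"
    mp.write_db(corpus_db, path)
    data = bytearray(path.read_bytes())
    data[0] ^= 0xFF
    path.write_bytes(bytes(data))
    with pytest.raises(CorruptionError):
        mp.read_db(path)


def test_corrupt_sentinel_names_record(tmp_path, corpus_db):
    path = tmp_path / "db.bin"
    mp.write_db(corpus_db, path)
    data = bytearray(path.read_bytes())
    # compute the sentinel offset of record k from the layout arithmetic
    k = len(corpus_db.records) // 2
    off = 9
    for rec in corpus_db.records[:k + 1]:
        off += sum(1 + 2 * len(level) for level in rec.environment.levels) + 9
    sentinel_off = off - 1
    assert data[sentinel_off] == SENTINEL
    data[sentinel_off] = 0x00
    path.write_bytes(bytes(data))
    with pytest.raises(CorruptionError) as err:
        mp.read_db(path)
    assert err.value.record_index == k


def test_truncated_file_detected(tmp_path, corpus_db):
    path = tmp_path / "db.bin"
    mp.write_db(corpus_db, path)
    path.write_bytes(path.read_bytes()[:-5])
    with pytest.raises(TruncationError):
        mp.read_db(path)


def test_count_wider_than_byte_clamps_with_warning(tmp_path):
    env = AtomEnvironment(-1, (((0, 1),), ((12, 300),), (), (), (), ()))
    db = mp.MetabDatabase(records=[mp.FingerprintRecord(env, 1, 2)])
    path = tmp_path / "db.bin"
    with pytest.warns(UserWarning, match="clamped"):
        mp.write_db(db, path)
    assert mp.read_db(path).records[0].environment.levels[1] == ((12, 255),)
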