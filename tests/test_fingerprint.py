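"""Circular environments: layer semantics vs a BFS oracle, hashing, similarity."""

import networkx as nx
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem

import metaprint2d as mp
from metaprint2d.atomtyping import SYBYL_TYPES
from metaprint2d.errors import ContractViolationError
from metaprint2d.fingerprint import AtomEnvironment, prefix_hash

C3 = mp.type_index("C.3")
H = mp.type_index("H")


def typed(smi):
    return mp.prepare(Chem.MolFromSmiles(smi))


def test_methane_levels():
    env = mp.compute_environment(typed("C"), 0, depth=3)
    assert env.levels == (((C3, 1),), ((H, 4),), ())


def test_ethane_levels():
    env = mp.compute_environment(typed("CC"), 0, depth=3)
    assert env.levels == (((C3, 1),), ((C3, 1), (H, 3)), ((H, 3),))


def test_centre_out_of_range():
    with pytest.raises(IndexError):
        mp.compute_environment(typed("C"), 99)


def bfs_oracle(mol: mp.TypedMolecule, centre: int, depth: int):
    """Independent layer derivation: networkx shortest-path distances."""
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((a, b) for a, b, _ in mol.bonds)
    dist = nx.single_source_shortest_path_length(g, centre, cutoff=depth - 1)
    levels = [{} for _ in range(depth)]
    types = mol.type_indices()
    for atom, d in dist.items():
        levels[d][types[atom]] = levels[d].get(types[atom], 0) + 1
    return tuple(tuple(sorted(l.items())) for l in levels)


def test_environments_match_bfs_oracle_over_scaffolds():
    from metaprint2d.fixtures import default_scaffolds

    for smi in default_scaffolds():
        mol = typed(smi)
        for env in mp.compute_all_environments(mol):
            assert env.levels == bfs_oracle(mol, env.centre_atom, 6), (smi, env.centre_atom)


def test_level_one_is_centre_type_only():
    mol = typed("CC(=O)Nc1ccc(O)cc1")
    for i, env in enumerate(mp.compute_all_environments(mol)):
        assert env.levels[0] == ((mol.atoms[i].type_index, 1),)


def test_layer_conservation_on_acyclic_molecule():
    # on a tree, with depth > eccentricity, every atom lands in exactly one layer
    for smi in ("CCO", "CC(C)=O", "CN"):
        mol = typed(smi)
        for env in mp.compute_all_environments(mol, 6):
            assert sum(c for level in env.levels for _, c in level) == mol.n_atoms


# --- hashing -----------------------------------------------------------------

level_entries = st.dictionaries(
    st.integers(0, len(SYBYL_TYPES) - 1), st.integers(1, 50), max_size=5
).map(lambda d: tuple(sorted(d.items())))


@st.composite
def environments(draw, depth=6):
    first = ((draw(st.integers(0, len(SYBYL_TYPES) - 1)), 1),)
    rest = tuple(draw(level_entries) for _ in range(depth - 1))
    return AtomEnvironment(centre_atom=0, levels=(first,) + rest)


@given(environments())
def test_hash_prefix_property(env):
    full = mp.hash_levels(env).hashes
    for d in range(1, env.depth + 1):
        assert mp.hash_levels(env.truncated(d)).hashes == full[:d]
        assert prefix_hash(env, d) == full[d - 1]


@given(environments())
def test_identical_environments_identical_hashes(env):
    clone = AtomEnvironment(centre_atom=17, levels=env.levels)
    assert mp.hash_levels(clone).hashes == mp.hash_levels(env).hashes


def test_hash_equality_refines_env_equality_over_corpus(corpus):
    records, _ = corpus
    by_levels = {}
    for rec in records:
        for env in mp.compute_all_environments(rec.reactant):
            by_levels.setdefault(env.levels, set()).add(mp.hash_levels(env).hashes)
    for hashes in by_levels.values():
        assert len(hashes) == 1  # equal fingerprints never differ in hash


def test_default_alpha_is_16():
    assert mp.SearchParams().alpha == 16


# --- similarity --------------------------------------------------------------


@given(environments(), environments())
def test_similar_reflexive_and_symmetric(a, b):
    params = mp.SearchParams(epsilon=3.0)
    assert mp.similar(a, a, params)
    assert mp.similar(a, b, params) == mp.similar(b, a, params)


def test_exact_level_mismatch_fails_regardless_of_epsilon():
    base = mp.compute_environment(typed("CCO"), 0)
    bumped = list(base.levels)
    bumped[1] = ((C3, 5),)  # level 2 differs; N=3 requires exact match there
    other = AtomEnvironment(0, tuple(bumped))
    assert not mp.similar(base, other, mp.SearchParams(epsilon=1e9))


def test_standard_mode_similarity_is_identity(corpus):
    records, _ = corpus
    envs = []
    seen = set()
    for rec in records[:30]:
        for env in mp.compute_all_environments(rec.reactant):
            if env.levels not in seen:
                seen.add(env.levels)
                envs.append(env)
    params = mp.SearchParams()  # epsilon = 0
    for a in envs[:80]:
        for b in envs[:80]:
            assert mp.similar(a, b, params) == (a.levels == b.levels)


def test_similar_is_not_transitive():
    shared = (((C3, 1),), ((H, 3),), ((C3, 2),))
    a = AtomEnvironment(0, shared + (((C3, 1),), (), ()))
    b = AtomEnvironment(0, shared + (((C3, 2),), (), ()))
    c = AtomEnvironment(0, shared + (((C3, 3),), (), ()))
    params = mp.SearchParams(epsilon=1.0)
    assert mp.similar(a, b, params) and mp.similar(b, c, params)
    assert not mp.similar(a, c, params)


def test_depth_mismatch_raises():
    a = mp.compute_environment(typed("CC"), 0, depth=4)
    b = mp.compute_environment(typed("CC"), 0, depth=6)
    with pytest.raises(ContractViolationError):
        mp.similar(a, b, mp.SearchParams())
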