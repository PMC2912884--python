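"""Layered circular atom environments and their level hashcodes.

An atom environment describes the neighbourhood of a centre atom as concentric
layers: level 1 is the centre atom itself, level 2 its bonded neighbours,
level 3 the atoms bonded to those, and so on.  Each level is a sparse count
vector over the Sybyl type ordinals.  Layers are generated breadth-first
with shortest-path semantics: an atom at graph distance d from the centre is
counted exactly once, in layer d+1, so ring back-edges never re-count atoms.

Per-level hashcodes give a compact prefix key for candidate lookup: the hash
at level L depends only on levels 1..L, and identical level prefixes always
hash identically.  Hash collisions between different environments are allowed
because candidates are always re-verified with :func:`similar`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .atomtyping import TypedMolecule
from .errors import ContractViolationError

#: Environments extend at most six layers out from the centre.
MAX_DEPTH = 6
DEFAULT_DEPTH = 6
#: Hash multiplier default.
DEFAULT_ALPHA = 16
#: Number of levels that must match exactly in similarity searches.
DEFAULT_N_EXACT = 3

_HASH_MOD = 1 << 64

#: One sparse level: ((type_index, count), ...) sorted by type_index.
Level = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class AtomEnvironment:
    """Sparse layered count vectors around one centre atom.

    ``levels[0]`` always contains exactly one entry with count 1 (the centre
    atom's own type).  Outer levels may be empty when the molecule is smaller
    than the requested depth.  ``centre_atom`` is -1 for environments restored
    from a serialised database, where the originating atom is not recorded.
    """

    centre_atom: int
    levels: tuple[Level, ...]

    @property
    def depth(self) -> int:
        return len(self.levels)

    def truncated(self, depth: int) -> "AtomEnvironment":
        """The same environment restricted to its first ``depth`` levels."""
        return AtomEnvironment(self.centre_atom, self.levels[:depth])


@dataclass(frozen=True)
class LevelHashes:
    """Cumulative per-level hashcodes of an environment."""

    hashes: tuple[int, ...]
    alpha: int = DEFAULT_ALPHA


@dataclass(frozen=True)
class SearchParams:
    """Similarity-search parameterisation.

    ``n_exact`` (N) levels must match exactly; deeper levels contribute a
    weighted L1 distance that must not exceed ``epsilon``.  The shipped
    defaults are depth 6, alpha 16 and N = 3; ``epsilon = 0`` is the
    "Standard" search mode (similar == identical), a positive ``epsilon``
    gives the "Fuzzy" mode.
    """

    n_exact: int = DEFAULT_N_EXACT
    epsilon: float = 0.0
    alpha: int = DEFAULT_ALPHA
    depth: int = DEFAULT_DEPTH
    weights: tuple[float, ...] | None = None  # per level 1..depth; None = all 1

    def __post_init__(self) -> None:
        if not 0 <= self.n_exact <= self.depth:
            raise ContractViolationError(
                f"n_exact must lie in [0, depth]; got {self.n_exact} with depth {self.depth}"
            )
        if self.epsilon < 0:
            raise ContractViolationError("epsilon must be >= 0")
        if not 1 <= self.depth <= MAX_DEPTH:
            raise ContractViolationError(f"depth must lie in [1, {MAX_DEPTH}]")
        if self.weights is not None:
            if len(self.weights) != self.depth:
                raise ContractViolationError("weights must have one entry per level")
            if any(w < 0 for w in self.weights):
                raise ContractViolationError("weights must be >= 0")

    def weight(self, level: int) -> float:
        """Weight of 1-based ``level`` (only levels > n_exact are ever used)."""
        return 1.0 if self.weights is None else self.weights[level - 1]

    @classmethod
    def fuzzy(cls, epsilon: float = 4.0, **kwargs) -> "SearchParams":
        return cls(epsilon=epsilon, **kwargs)


def compute_environment(mol: TypedMolecule, centre: int, depth: int = DEFAULT_DEPTH) -> AtomEnvironment:
    """Breadth-first layered environment of ``centre`` out to ``depth`` levels.

    Levels beyond the molecule's extent are present but empty, so all
    environments of a given depth are directly comparable.
    """
    if not 0 <= centre < mol.n_atoms:
        raise IndexError(f"centre atom {centre} out of range for {mol.n_atoms} atoms")
    if not 1 <= depth <= MAX_DEPTH:
        raise ValueError(f"depth must lie in [1, {MAX_DEPTH}]; got {depth}")
    adj = mol.adjacency()
    types = mol.type_indices()
    counts: list[Counter] = [Counter() for _ in range(depth)]
    seen = {centre}
    frontier = [centre]
    counts[0][types[centre]] += 1
    for level in range(1, depth):
        nxt: list[int] = []
        for a in frontier:
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    nxt.append(b)
                    counts[level][types[b]] += 1
        frontier = nxt
        if not frontier:
            break
    levels = tuple(tuple(sorted(c.items())) for c in counts)
    return AtomEnvironment(centre_atom=centre, levels=levels)


def compute_all_environments(mol: TypedMolecule, depth: int = DEFAULT_DEPTH) -> tuple[AtomEnvironment, ...]:
    """Environments for every atom, memoised on the molecule."""
    cached = mol._env_cache.get(depth)
    if cached is None:
        cached = tuple(compute_environment(mol, i, depth) for i in range(mol.n_atoms))
        mol._env_cache[depth] = cached
    return cached


def _level_polynomial(level: Level) -> int:
    # odd multipliers keep distinct type indices from aliasing at small counts
    return sum(count * (2 * idx + 1) for idx, count in level)


def hash_levels(env: AtomEnvironment, alpha: int = DEFAULT_ALPHA) -> LevelHashes:
    """Cumulative hashcodes, one per level.

    ``h_0 = 0; h_L = (alpha * h_{L-1} + p_L) mod 2^64`` where ``p_L`` folds the
    level-L sparse counts.  The hash at level L is a function of levels 1..L
    only, so truncation commutes with hashing (prefix property), and identical
    level prefixes always collide — the lookup loses no true matches.
    """
    hashes: list[int] = []
    h = 0
    for level in env.levels:
        h = (alpha * h + _level_polynomial(level)) % _HASH_MOD
        hashes.append(h)
    return LevelHashes(hashes=tuple(hashes), alpha=alpha)


def prefix_hash(env: AtomEnvironment, n_levels: int, alpha: int = DEFAULT_ALPHA) -> int:
    """Hash of the first ``n_levels`` levels (the candidate-lookup key)."""
    h = 0
    for level in env.levels[:n_levels]:
        h = (alpha * h + _level_polynomial(level)) % _HASH_MOD
    return h


def _level_l1(a: Level, b: Level) -> int:
    da = dict(a)
    dist = 0
    for idx, count in b:
        dist += abs(da.pop(idx, 0) - count)
    dist += sum(da.values())
    return dist


def similar(fq: AtomEnvironment, ft: AtomEnvironment, params: SearchParams) -> bool:
    """Whether a query environment matches a stored one.

    True iff levels 1..N are identical count vectors and the weighted L1
    distance summed over the remaining levels is at most ``epsilon``.  With
    ``epsilon = 0`` and positive weights this degenerates to full identity.
    """
    if fq.depth != ft.depth:
        raise ContractViolationError(
            f"environment depths differ: {fq.depth} vs {ft.depth}"
        )
    n = params.n_exact
    if fq.levels[:n] != ft.levels[:n]:
        return False
    dist = 0.0
    for l in range(n, fq.depth):
        if fq.levels[l] != ft.levels[l]:
            dist += params.weight(l + 1) * _level_l1(fq.levels[l], ft.levels[l])
            if dist > params.epsilon:
                return False
    return dist <= params.epsilon
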