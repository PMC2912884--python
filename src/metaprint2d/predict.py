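"""Per-atom site-of-metabolism scoring against a fingerprint database.

Each query atom's environment is matched against the database; the sums of
reaction-centre (rc) and overall (oc) counts over all similar stored
environments give an occurrence ratio rc_sum/oc_sum — how often environments
like this one sat at a reaction centre, relative to how often they were seen
at all.  Ratios are normalised by the molecule's maximum so the most likely
site of metabolism scores a normalised occurrence ratio (NOR) of one, and
banded for display (high/medium/low/very_low); atoms whose environment was
never observed are "no_data" rather than zero — absence of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .atomtyping import SYBYL_TYPES, TypedMolecule
from .dbbuild import FingerprintRecord, MetabDatabase
from .errors import ContractViolationError, IncompatibilityError
from .fingerprint import (
    AtomEnvironment,
    SearchParams,
    compute_all_environments,
    prefix_hash,
    similar,
)

__all__ = [
    "SearchParams", "AtomPrediction", "BandThresholds",
    "find_similar", "predict_atoms", "normalise_predictions", "band_of",
]

#: Display bands in decreasing likelihood order.
BANDS = ("high", "medium", "low", "very_low", "no_data")


@dataclass(frozen=True)
class BandThresholds:
    """NOR cut points for the colour bands (display config, not science)."""

    high: float = 0.66
    medium: float = 0.33
    low: float = 0.15


DEFAULT_BANDS = BandThresholds()


@dataclass(frozen=True)
class AtomPrediction:
    """Scores for one query atom."""

    atom_index: int
    rc_sum: int
    oc_sum: int
    ratio: float | None  # undefined when oc_sum == 0
    nor: float | None    # normalised occurrence ratio in [0, 1]
    band: str


def band_of(nor: float | None, thresholds: BandThresholds = DEFAULT_BANDS) -> str:
    """Monotone step banding of a NOR value; undefined -> ``no_data``."""
    if nor is None:
        return "no_data"
    if not 0.0 <= nor <= 1.0:
        raise ContractViolationError(f"nor must lie in [0, 1]; got {nor}")
    if nor >= thresholds.high:
        return "high"
    if nor >= thresholds.medium:
        return "medium"
    if nor >= thresholds.low:
        return "low"
    return "very_low"


def find_similar(
    db: MetabDatabase,
    fq: AtomEnvironment,
    params: SearchParams = SearchParams(),
) -> list[FingerprintRecord]:
    """All stored records whose environment is similar to ``fq``.

    The level-N prefix hash prunes candidates; every candidate is re-verified
    with :func:`~metaprint2d.fingerprint.similar`, so pruning loses no true
    match (identical N-level prefixes always share a hash).
    """
    if fq.depth != db.n_levels:
        raise IncompatibilityError(
            f"query depth {fq.depth} != database depth {db.n_levels}"
        )
    if params.depth != db.n_levels:
        raise IncompatibilityError(
            f"search depth {params.depth} != database depth {db.n_levels}"
        )
    index = db.hash_index(params.n_exact, params.alpha)
    key = prefix_hash(fq, params.n_exact, params.alpha)
    return [
        db.records[i]
        for i in index.get(key, ())
        if similar(fq, db.records[i].environment, params)
    ]


def normalise_predictions(
    preds: list[AtomPrediction],
    thresholds: BandThresholds = DEFAULT_BANDS,
) -> list[AtomPrediction]:
    """Scale ratios so the molecule's maximum defined ratio maps to NOR 1.

    Ties all share NOR 1.  If every defined ratio is zero (matched atoms, none
    ever a reaction centre) NOR is 0 for those atoms; if no atom matched at
    all, NOR stays undefined everywhere.
    """
    defined = [p.ratio for p in preds if p.ratio is not None]
    max_ratio = max(defined) if defined else None
    out: list[AtomPrediction] = []
    for p in preds:
        if p.ratio is None:
            nor = None
        elif max_ratio and max_ratio > 0:
            nor = p.ratio / max_ratio
        else:
            nor = 0.0
        out.append(replace(p, nor=nor, band=band_of(nor, thresholds)))
    return out


def predict_atoms(
    db: MetabDatabase,
    mol: TypedMolecule,
    params: SearchParams = SearchParams(),
    thresholds: BandThresholds = DEFAULT_BANDS,
) -> list[AtomPrediction]:
    """Score every atom of a typed query molecule.

    Per atom: rc_sum and oc_sum are summed over all similar stored records;
    ratio = rc_sum/oc_sum where oc_sum > 0; NOR and band follow from
    :func:`normalise_predictions`.
    """
    if tuple(db.type_table) not in ((), SYBYL_TYPES):
        raise IncompatibilityError("database type table differs from the Sybyl table")
    preds: list[AtomPrediction] = []
    for env in compute_all_environments(mol, db.n_levels):
        rc_sum = 0
        oc_sum = 0
        for rec in find_similar(db, env, params):
            rc_sum += rec.rc
            oc_sum += rec.oc
        ratio = rc_sum / oc_sum if oc_sum > 0 else None
        preds.append(AtomPrediction(
            atom_index=env.centre_atom, rc_sum=rc_sum, oc_sum=oc_sum,
            ratio=ratio, nor=None, band="no_data",
        ))
    return normalise_predictions(preds, thresholds)
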