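# metaprint2d

Site-of-metabolism (SoM) prediction for small molecules from circular
atom-environment fingerprints.

Medicinal chemists routinely need to know *where* on a candidate molecule
Phase I metabolic enzymes (chiefly cytochrome P450s) are likely to act —
hydroxylations, dealkylations, epoxidations and hydrolyses determine a
compound's clearance, active metabolites and toxicity. `metaprint2d`
implements a data-driven answer: mine a corpus of known, atom-mapped
biotransformations for the atom environments that sat at reaction centres,
then rank the atoms of a query molecule by how often *similar* environments
were metabolised.

## Method

**Database build.** Each transformation record (reactant → product, sharing
atom-map numbers) is diffed and classified: *additions* of exactly one oxygen
(hydroxylation, oxidation, epoxidation) mark the oxygen's neighbour(s) as
reaction centres; *eliminations* (dealkylation, ester/amide hydrolysis) mark
both endpoints of each broken bond; everything else — bond-order-only changes
and Phase II conjugations — is rejected. For every reactant atom a layered
circular fingerprint is computed: concentric layers out to depth 6, each a
sparse count vector over Sybyl (Tripos) atom types, which combine element,
hybridisation and aromaticity (`C.ar`, `N.am`, `O.3`, …). Hydrogens are
explicit, typed atoms. For every unique fingerprint `F` the database stores

- `rc(F)` — occurrences at a reaction centre, and
- `oc(F)` — occurrences anywhere in a reactant,

so `rc ≤ oc` holds by construction.

**Prediction.** For every atom *a* of a query, with fingerprint `F^q`, the
database is searched for similar stored fingerprints `F^t`: the first *N* = 3
levels must match exactly, and deeper levels may differ by a weighted L1
distance of at most ε (ε = 0 in the default "Standard" mode). Per-level
hashcodes `h_L = (α·h_{L−1} + p_L) mod 2⁶⁴` with α = 16 prune candidates
without losing any true match, since identical level prefixes always share a
hash. The atom's score is the **occurrence ratio**

    ratio(a) = Σ rc(F^t) / Σ oc(F^t)

over all similar records, scaled within the molecule so its most likely site
gets a **normalised occurrence ratio (NOR)** of 1, then banded
high / medium / low / very_low for display; atoms whose environment was never
observed are `no_data`. No claim is made about *whether* the molecule is
metabolised — only the relative ranking of sites.

Proprietary reaction databases are not required: `metaprint2d.fixtures`
generates reproducible synthetic corpora of mapped Phase I transformations
(seven reaction classes over a curated drug-like scaffold pool, with species
tags and ground-truth centres in a sidecar), which is how the test suite and
the acceptance script exercise the full pipeline.

## Worked example

```python
from rdkit import Chem
import metaprint2d as mp

# 300 synthetic mapped Phase I transformations -> fingerprint database
records, _ = mp.generate_corpus(mp.FixtureSpec(n_records=300, seed=5))
db = mp.build_database(records)

query = mp.prepare(Chem.MolFromSmiles("CCOc1ccc(NC(=O)C)cc1"), title="phenacetin")
for p in sorted(mp.predict_atoms(db, query), key=lambda p: -(p.nor or 0))[:5]:
    print(f"atom {p.atom_index:2d} {query.atoms[p.atom_index].sybyl_type:5s} "
          f"rc={p.rc_sum:3d} oc={p.oc_sum:3d} ratio={p.ratio:.3f} nor={p.nor:.3f} {p.band}")
```

```
atom  7 N.am  rc=  9 oc= 26 ratio=0.346 nor=1.000 high
atom  8 C.2   rc=  9 oc= 26 ratio=0.346 nor=1.000 high
atom 10 C.3   rc=  3 oc= 26 ratio=0.115 nor=0.333 medium
atom  0 C.3   rc=  1 oc= 11 ratio=0.091 nor=0.263 low
atom  1 C.3   rc=  1 oc= 11 ratio=0.091 nor=0.263 low
```

The amide nitrogen and carbonyl carbon — the two endpoints cleaved by amide
hydrolysis — tie at NOR 1: against this corpus, phenacetin's most likely site
of metabolism. Per atom you get the reaction-centre hit count, total hit
count, occurrence ratio, NOR and band.

The same pipeline from the shell:

```sh
metaprint2d make-fixtures --out corpus --seed 5 --n-records 300
metaprint2d build-db --reactions corpus/reactions.smi --out all.db
metaprint2d build-db --reactions corpus/reactions.smi --out human.db --species human
metaprint2d predict --db all.db --in query.smi --out pred.tsv          # or --format sdf
```

SDF batch output attaches `MetaPrint2D_NOR`, `MetaPrint2D_Bands` and
`MetaPrint2D_RC_OC` properties to every record.

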