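# Methods

## Model

`metaprint2d` scores sites of Phase I metabolism by nearest-environment
statistics, not by any mechanistic or quantum-chemical model. The unit of
evidence is the *circular atom environment*: concentric layers around a
centre atom, each layer a sparse count vector of Sybyl atom types. Layer 1 is
the centre's own type; an atom at topological distance *d* is counted once,
in layer *d* + 1 (shortest-path layering — ring back-edges never re-count an
atom, and the centre never reappears in outer layers). Environments extend to
depth 6; layers beyond the molecule's extent are present but empty, so all
depth-6 environments are directly comparable.

The underlying assumptions, shared with all fingerprint-similarity SoM
methods:

- metabolic regioselectivity is largely determined by the local (≤ 6 bond)
  topological neighbourhood of an atom, typed by element, hybridisation and
  aromaticity;
- frequencies in a transformation corpus are a usable proxy for likelihood —
  the method reports evidence ratios, not rates, and deliberately makes no
  claim about whether the molecule is metabolised at all.

## Atom typing

Types come from the fixed 33-member Sybyl table (serialised ordinals; order
frozen). Assignments follow the published Tripos conventions: carbonyl O →
`O.2`, carboxylate and phosphate terminal O → `O.CO2`, amide (and thioamide)
N → `N.am`, planar trisubstituted N → `N.pl3`, charged sp3 N → `N.4`,
sulfoxide → `S.O`, sulfone → `S.O2`, guanidinium C → `C.cat`. Points the
Tripos definitions leave open were fixed as follows: nitro N is `N.pl3` and
its charged oxygens `O.2` (the common mol2 convention); N-oxide O⁻ is `O.2`;
aromatic O/S (furan, thiophene) fall back to `O.3`/`S.3` since the table has
no aromatic type for them. `LP` and `Du` are accepted in serialised databases
but never emitted for real structures; elements outside the table map to
`Du`. RDKit's default aromaticity perception is used on both the build and
the query path — only internal consistency matters, so one model is used
everywhere. Hydrogens are explicit atoms throughout: `H` is a table member
and hydrogen shells are part of every environment. Typing is cross-checked
in the test suite against Open Babel's independent MOL2 Sybyl typer on
verapamil (atom-for-atom agreement on all 33 heavy atoms).

## Hashing and similarity

Stored per level: `h_0 = 0`, `h_L = (α·h_{L−1} + p_L) mod 2⁶⁴` with
`p_L = Σ_i s_i·(2i+1)`, where `s_i` is the count of type ordinal `i` in layer
`L` and α = 16. The only property the pipeline relies on is the prefix
property — the hash at level L is a function of layers 1..L, so identical
prefixes always collide — which makes hash lookup a lossless pruning step:
candidates sharing the level-N prefix hash are re-verified exactly.  The odd
multipliers `2i+1` merely reduce accidental collisions; any collision is
harmless because of re-verification, and this is confirmed at scale by the
acceptance check comparing indexed search with a brute-force linear scan.

Similarity of query `F^q` and stored `F^t`: layers 1..N identical as count
vectors, and `Σ_{l>N} w_l·‖F^q_l − F^t_l‖₁ ≤ ε`. Defaults: N = 3, all
`w_l = 1`, ε = 0 ("Standard" mode, where similarity degenerates to identity
of all six layers); "Fuzzy" mode is ε > 0 (CLI default ε = 4 when selected).
ε and the weights are exposed configuration: nothing in the scoring maths
depends on their particular values, and Standard mode is the reproducible
reference. The similarity relation is reflexive and symmetric but *not*
transitive in fuzzy mode (two small steps can exceed ε); a counterexample is
kept under test.

## Database build

Every reactant atom of every record — including rejected ones — increments
its environment's overall count `oc`; reaction-centre atoms of accepted
records increment `rc`. Counting all reactants (not only accepted records)
is the default because the denominator is meant to capture how often an
environment is *seen*, metabolised or not; `count_all_reactants=False` is
available for the narrower convention. "Bonds made" between mapped atoms
never mark centres: only single-oxygen additions and bond cleavages are
retained, so a desaturation (bond-order change only) is rejected.

Classification order matters: a broken mapped–mapped bond is checked before
the single-added-oxygen test, because a hydrolysis whose products are kept
concatenated (acid + alcohol) adds one water-derived oxygen *and* breaks a
bond — it is an elimination. A bond both of whose endpoints leave with a
departing fragment is not counted as broken (the fragment left intact);
this keeps dealkylations and hydrolyses at exactly two centres each.

Serialisation is a sparse big-endian layout (magic `MP2D`, u32 record count,
u8 level count; per record: per level a u8 entry count plus (u8 type ordinal,
u8 count) pairs; i32 `rc`; i32 `oc`; sentinel byte `0xAB`). Counts wider than
a byte clamp to 255 with a warning — at that magnitude the ratio is
insensitive to the clamp. The sentinel gives cheap per-record corruption
detection with the failing record index; truncation is reported separately.
Species labels are metadata outside the binary layout.

## Prediction

`ratio(a) = Σ rc / Σ oc` over similar records; undefined (not zero) when no
record matches — an unseen environment carries no evidence either way, so
`no_data` is distinct from a confidently low score. NORs divide by the
molecule's maximum defined ratio; ties all receive 1. The degenerate case
where atoms matched but every defined ratio is 0 yields NOR 0 (no positive
evidence anywhere in the molecule). Hydrogen atoms are scored and normalised
like heavy atoms, since their environments are first-class. Band thresholds
(high ≥ 0.66 > medium ≥ 0.33 > low ≥ 0.15 > very_low) are display
configuration, not science, and are a `BandThresholds` parameter.

## Synthetic corpora

The generator emulates the *machinery* of a curated metabolic-transformation
database: fully atom-mapped reactant→product pairs over seven Phase I classes
(aromatic/aliphatic hydroxylation, epoxidation, O-/N-dealkylation,
ester/amide hydrolysis), species tags, and optional Phase II "poison" records
(glucuronidation, sulfation) that a correct builder must reject. The default
class mix (0.25/0.25/0.05/0.15/0.15/0.08/0.07) reflects the broad shape of
drug metabolism — CYP hydroxylations dominate, epoxidations are rare — and
the species mix (human 0.5 / rat 0.3 / dog 0.2) the typical composition of
literature-curated data. The scaffold pool is 20 curated drug-like molecules
(including verapamil); a 50-drug extended pool supplies experiments needing
many distinct reactants, with light halogen/methyl decoration beyond that.
Ground-truth centres travel in a sidecar table as atom-map numbers (maps
survive SMILES round-trips; raw indices do not), never inside the records
themselves.

What the corpus does *not* emulate: real regioselectivity statistics,
steric/electronic activation, multi-step metabolism, or the scale and
redundancy of literature data. Passing tests therefore demonstrate that the
machinery is correct — diffing, counting, searching, normalising — not that
predictions on real drugs are accurate; accuracy inherits entirely from
whatever transformation corpus the database is built from.

## Problem sizes and numerical choices

The scale checks use a 10⁴-record corpus (about 340 unique environments over
the 20-scaffold pool — the generator memoises repeated scaffold/site
variants, so database build is count accumulation, not repeated RDKit work)
with 200 query molecules verified atom-by-atom against a vectorised
brute-force scan; recovery checks use 500 mixed records plus 50 poison
records; round-trips cover 1/100/10⁴-record databases; the self-recovery
experiment trains on 50 single-centre hydroxylations, one per distinct
reactant, because with repeated reactants the "true centre on top" guarantee
is statistically false (a molecule carrying several recorded sites dilutes
symmetric positions below its best site — correct behaviour of the scoring,
not an artefact). Exact integer counts are kept end to end; the only
floating-point quantities are ratios and NORs, and `max(nor) == 1.0` is exact
because the maximal ratio divides itself.

## Known limitations

- Exact Standard-mode matching is brittle for sparse databases: a query atom
  whose 6-layer environment was never seen verbatim scores `no_data` even if
  a near-identical environment exists; fuzzy mode trades this for looser
  matching.
- Byte-wide serialised counts clamp at 255 per type per layer.
- No automatic atom-atom mapping: input reactions must carry curated maps.
- No tautomer/protonation-state handling; whichever form is supplied is the
  form that is typed.
- Phase II metabolism is out of scope by design; conjugation records are
  rejected during build.
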