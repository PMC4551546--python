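# Methods

This note documents the models, procedures and numerical choices behind
qsarkit, in the order the pipeline runs them.

## Compound standardisation

A molecule passes through: parse → keep largest covalent fragment →
inorganic filter → per-element halogen limits → molecular-mass window →
tautomer canonicalisation. Each rejected molecule is labelled with the
first filter that removed it, so the partition of statuses is reproducible;
this required fixing an order, and the one above runs the cheap structural
checks before the InChI round trip.

Decisions taken where the field has no single convention:

- **Inorganic** means *contains no carbon atom* — the conventional
  cheminformatics rule, and a testable one.
- **Halogen limits are per element** (F, Cl, Br, I separately), compared
  strictly: count > limit → removed. This is what lets a dataset biased
  toward, say, heavily fluorinated compounds be normalised without touching
  chlorinated ones.
- **Salts/mixtures**: the largest covalent fragment is kept before any
  filter (toggleable via `keep_largest_fragment`). An acetate salt is
  therefore an organic molecule, while `[Na+].[Cl-]` reduces to a single
  inorganic ion and is removed when the inorganic filter is on.
- **Tautomers** are collapsed by converting to standard InChI and back.
  Standard InChI's mobile-H layer covers N/O/S-bound protons only, so
  heteroatom tautomer families (pyridone/hydroxypyridine, amide/imidic
  acid, imidazole NH shifts) converge to one canonical SMILES, while
  keto–enol pairs — whose mobile proton sits on carbon — do not. The
  contract is convergence of equivalent structures, not any particular
  SMILES dialect; the output string is whatever the toolkit's canonical
  writer produces after the round trip.

## Descriptors

Physicochemical engines are a registry; two are bundled. `rdkit` is the
host toolkit's full 1D/2D list (~210 descriptors, no conformers). `rdkit_minimal`
is a 15-column count/property set (heavy atoms, rings, aromatic rings,
rotatable bonds, H-bond donors/acceptors, TPSA, logP, molecular weight,
N/O and per-halogen counts). The compact engine exists because a linear
property generated from a handful of interpretable columns should be
recoverable *exactly* through the pipeline: with p ≪ n the final
least-squares fit is well-posed and the end-to-end test can assert RMSE at
numerical precision rather than "small". The engine name and toolkit
version are recorded in every matrix's provenance and in the model bundle;
external prediction refuses to run under a different toolkit version.

Morgan fingerprints use the radius convention (a maximal substructure
*diameter* of 4 bonds = radius 2). Hashed fingerprints fold environment
identifiers into a fixed width, binary or count. Unhashed fingerprints fix
a `FingerprintBasis` — the sorted union of all environment identifiers of
radius 0..r in the training set — and every later matrix is expressed on
those columns in basis order. Substructures absent from the basis are
silently dropped, so an external molecule sharing no chemistry with the
training set yields an all-zero row and still gets a prediction. The
environment identifiers are the toolkit's canonical Morgan ids; the
contract is internal consistency within one recorded engine version, not
cross-toolkit stability.

Protein-side descriptors target proteochemometrics. Aligned binding-site
sequences are encoded per position with a scale table (bundled: the
3-dimensional Hellberg z-scales and the 5-dimensional Sandberg extension);
a gap contributes exactly `dims` zeros, which keeps all rows the same
length and makes an all-gap column identically zero. Non-standard residue
letters (B, Z, X, U) are rejected rather than zero-filled — gaps are the
only sanctioned zero-encoding, and silently zeroing an unknown residue
would fabricate signal. Other published scale sets load from user CSVs
instead of being bundled, since a registry keeps the API complete without
shipping tables of uncertain provenance. Whole-sequence composition
descriptors (AAC, 20 columns; DC over the L−1 overlapping dipeptides, 400
columns) are *relative frequencies* summing to one — frequency rather than
raw counts so sequences of different lengths are comparable.

## Preprocessing

Fixed order: impute → near-zero-variance → correlation filter →
centre/scale. Choices:

- **Imputation** is the column mean over observed training entries — the
  simplest deterministic, replayable rule. A column with no observed value
  is an error, not a guess.
- **Near-zero variance**: a column is dropped iff its
  most-frequent/second-most-frequent count ratio strictly exceeds
  `freq_cut` (default 30, infinite for constants) *and* its percentage of
  distinct values is ≤ `unique_cut` (default 10%). The second criterion
  protects continuous columns that merely have a popular value; it is
  configurable and documented here as this package's defaults.
- **Correlation filter**: repeatedly find the pair with the largest
  |Pearson r| above the cutoff (default 0.95) and drop, from that pair,
  the member with the larger mean absolute correlation to the remaining
  columns; ties go to the larger column index. Deterministic, and
  guarantees the surviving matrix has no pair above the cutoff.
  Fingerprint columns pass through the same filters as physicochemical
  ones.
- **Centre/scale** uses the sample standard deviation (n−1 denominator).

The fitted output is produced *by replaying the state*, so fit and
external application share one code path and the training matrix replays
bit-identically — the invariant the external-prediction contract rests on.

## Splitting, cross-validation, training

`split_set` holds out round(fraction·n) training samples (default fraction
0.8); the stratified variant ranks the response into 5 quantile bins and
allocates proportionally (floor + largest remainders), so both subsets
cover the response range. `make_folds` assigns folds round-robin over a
shuffled permutation (sizes differ by ≤1), or within quantile bins for the
stratified variant. Hyper-parameter grids are explicit lists; `exp_grid`
builds the usual exponential ladders. Grid-search CV fits every
combination on k−1 folds, predicts the held-out fold, and selects the
combination with the lowest mean RMSE across folds (mean q² selection is
available); ties keep the earliest combination in grid order. Out-of-fold
predictions are retained per combination because ensembles are built on
them. Learners are scikit-learn estimators behind a name registry; seeds
are injected into every stochastic learner, making the whole pipeline
bit-reproducible for a fixed seed.

For compound×target activity tables, duplicated (compound, target)
measurements are aggregated by the arithmetic mean before modelling, and
`matrix_completeness` reports 100·datapoints/(compounds·targets) to one
decimal.

## Ensembles

Greedy selection keeps an integer count per model, all starting at zero.
Each round evaluates, for every model, the RMSE of the count-normalised
weighted out-of-fold prediction with that model's count incremented by
one; the best increment (ties → lowest column index) is accepted only if
it *strictly* lowers the current RMSE. The first round therefore picks the
single best model; a round with no improving increment is terminal
(the procedure is deterministic, so later rounds would repeat it), and the
final weights are the normalised counts. Consequences asserted in tests:
the RMSE trace is non-increasing, the final ensemble is at least as good
as the best single model on the optimisation data, and permuting model
columns permutes the weights. Strict improvement (rather than accepting
RMSE-neutral increments) is the reading under which duplicated model
columns cleanly resolve to the first column.

Stacking fits a registry meta-learner on the out-of-fold matrix; if a
`meta_grid` is given its hyper-parameters are tuned with the *same* fold
assignment as the base models, extending the identical-fold-composition
requirement to the meta level. When the fitted meta-learner exposes
coefficients or feature importances, they are reported per base model.

## Validation statistics

The cross-validated q² compares squared residuals to scatter about the
*training* mean; RMSE is √(Σ(y−ŷ)²/N) — the summation is written
explicitly here because it is the only reading that yields a scalar. On
the test set, three explained-variance variants are reported (reference:
training mean, test mean, or training variance per case), plus Pearson R,
the least-squares slope through the origin of observed on predicted
k = Σy·ŷ/Σŷ², and R²₀ computed from the origin-constrained predictions
k·ŷ. R²_test in the acceptability criteria is R² — the square of the
Pearson correlation — since no separate definition exists. Degenerate
inputs (zero response variance, all-zero predictions) raise explicit
errors instead of returning NaN.

The achievable-performance bounds treat the experimental uncertainty as a
zero-mean Gaussian with user-supplied sd (the user's estimate, in response
units). Each repetition draws a test-sized sample from the response pool —
without replacement when it fits, with replacement otherwise — adds noise,
and scores sample against noisy sample (maximum performance), or permutes
the sample first so predictions carry no signal (minimum performance).
All three Q² variants are emitted, with the pool mean/variance serving as
the training reference. With noise 0 the maximum-performance distributions
are degenerate (RMSE 0, R = R²₀ = 1); at noise σ the mean best-case RMSE
converges to σ, and the worst-case R distribution is centred on zero —
both checked against their Monte-Carlo standard errors in the tests.

## Synthetic fixtures

The QSPR generator enumerates a fixed, duplicate-free list of small
achiral organics (alkane chains with O/N/halogen/acid/nitrile/alkene
terminations, benzene/pyridine/cyclohexane rings and their alkyl/phenol/
aniline/chloro variants, diols, dichlorides, amino acids) — parseable by
construction and stereochemistry-free so canonicalisation assertions stay
exact. The property is a linear combination of `rdkit_minimal` columns
(defaults: 0.35·heavy atoms − 0.9·Cl count + 0.7·rings + 0.5·H-bond
donors) plus Gaussian noise (default sd 0.1); the default coefficient
columns were chosen to be mutually decorrelated on the enumeration
(max |r| to any other compact-engine column ≈ 0.93 < 0.95), so they
survive the correlation filter and a noise-free fixture is exactly
recoverable end-to-end. Known heteroatom tautomer pairs can be appended
to exercise standardisation convergence.

The PCM generator adds synthetic aligned sequences (a random consensus
with per-target mutations and a deletion in every third target) and builds
activity = compound term + 0.8·(mean z1 of the target's residues) +
0.05·interaction + noise. Exactly ⌈completeness·n·T⌉ distinct cells are
retained (the product is rounded before the ceiling so 0.139·1000 yields
139 cells, not 140), with every compound and target covered when the
budget allows, and the first five cells are duplicated with a second noisy
measurement to exercise mean aggregation.

What the fixtures do *not* emulate: realistic chemical-space coverage,
activity cliffs, assay heterogeneity, inter-laboratory noise structure, or
the descriptor collinearity patterns of large real libraries. Passing
tests demonstrate the machinery is correct and replayable, not that any
particular real dataset will model well.

## Problem sizes and limitations

Tests and the acceptance script run at deliberately small scale — fixtures
of 100–200 molecules, 5-fold CV, 1000-repetition bounds — sizes chosen so
the full suite completes in seconds while every statistical assertion
still has the power it needs (Monte-Carlo checks are asserted against
their own standard errors, not fixed tolerances).

Known limitations: no 3-D descriptors or conformer handling; no
classification; hyper-parameter search is grid-only; binding-site
extraction from structures is out of scope (the protein module consumes an
already-extracted alignment); tautomer canonicalisation inherits standard
InChI's scope (no keto–enol collapsing); unhashed-basis identifiers are
stable only within one recorded toolkit version.
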