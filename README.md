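# qsarkit

Small-molecule property and bioactivity modelling (QSAR/QSPR and
proteochemometrics) as one reproducible pipeline: compound standardisation →
molecular and protein descriptors → fit-and-replay preprocessing →
cross-validated training → model ensembles → statistical validation →
prediction for new molecules.

## Who it is for

Modellers who need to go from a file of structures with measured properties
(aqueous solubility, pIC50, …) to a validated regression model — and then
apply that model to new compounds with *exactly* the training-time
processing. Every fitted fact (standardisation options, descriptor engine
and parameters, the unhashed-fingerprint basis, imputation means, dropped
columns, centres/scales, the fitted learner) lives in one self-contained
model bundle, so external prediction is a pure replay.

## What is inside

**Standardisation** (`qsarkit.standardize`). Structures are reduced to their
largest covalent fragment, filtered (per-element halogen limits, molecular
mass window, inorganic = no carbon atom), and tautomers are collapsed by a
standard-InChI round trip: N/O/S mobile hydrogens land in InChI's
delocalised layer, so every member of a tautomer family maps to a single
canonical SMILES. Removed molecules keep an explanatory status; the filter
order (parse → inorganic → halogen → mass → canonicalise) is fixed, so
statuses are reproducible.

**Descriptors** (`qsarkit.descriptors`, `qsarkit.protein`). Physicochemical
1D/2D descriptor engines (the full RDKit set, ~210 columns, or a compact
count-based set), and Morgan circular fingerprints — hashed
(binary/count, fixed width) or *unhashed*: each substructure observed in the
training set gets its own column, fixed by a persistent basis of Morgan
environment identifiers, so model coefficients stay attached to concrete
substructures and external molecules with unseen chemistry are zero-padded
rather than rejected. For proteochemometrics, aligned binding-site
sequences become per-position z-scale descriptors (gaps encode as zeros),
plus amino-acid and dipeptide composition for whole sequences.

**Preprocessing** (`qsarkit.preprocess`). Mean imputation, the classic
near-zero-variance filter (drop iff most-frequent/second-most-frequent
count ratio > 30 *and* distinct values ≤ 10%), greedy removal of descriptor
pairs with |r| > 0.95, then centring/unit-variance scaling — all recorded
in a `PreprocessState` whose replay on the training matrix is bit-identical
to the fit.

**Training and validation** (`qsarkit.cv`, `qsarkit.ensemble`,
`qsarkit.validate`). Random or response-stratified train/test splits and
k-fold assignments, exponential hyper-parameter grids, grid-search CV
minimising mean RMSE across folds, and a pluggable learner registry (RF,
GBM, SVR, kernel ridge, elastic net, …). Out-of-fold predictions feed two
ensemble builders: greedy selection (integer count increments accepted only
on strict RMSE improvement; the RMSE trace is non-increasing and the final
ensemble is never worse than the best single model on the optimisation
data) and stacking with any registered meta-learner. Validation implements

    q²_CV  = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ_tr)²          RMSE = √(Σ(yᵢ−ŷᵢ)²/N)
    Q²₁ (vs ȳ_tr) · Q²₂ (vs ȳ_test) · Q²₃ (PRESS/N_test over SS_tr/N_tr)
    R (Pearson) · k = Σy·ŷ/Σŷ² · R²₀ = 1 − Σ(y−kŷ)²/Σ(y−ȳ_test)²

and the Tropsha–Golbraikh acceptability criteria (q²_CV > 0.5,
R²_test > 0.6, (R²_test−R²₀)/R²_test < 0.1, 0.85 ≤ k ≤ 1.15), plus
Monte-Carlo *maximum/minimum achievable performance* distributions given
the experimental uncertainty of the response.

## Worked example

```python
from qsarkit import QsarModel, WorkflowConfig, DescriptorConfig
from qsarkit.synthetic import SyntheticSpec, make_qspr_fixture

table, truth = make_qspr_fixture(SyntheticSpec(n_molecules=120, noise_sd=0.3, seed=5))
cfg = WorkflowConfig(
    descriptors=DescriptorConfig(physchem="rdkit_minimal"),
    learners={"linear": None, "rf": {"n_estimators": [60]}, "knn": {"n_neighbors": [3, 5]}},
)
results = QsarModel.from_dataframe(table, config=cfg).fit(seed=4)
results.add_greedy_ensemble()
results.add_stacking_ensemble("linear")
print(results.summary())
```

prints

```
QSAR/QSPR workflow results
==========================
molecules kept: 120  (train 96, test 24)
folds: 5 (random), seed 4
descriptor engine: 2024.09.2

       model  rmse_cv  r2_cv  rmse_test  r2_0_test  r2_test
      linear    0.309  0.927      0.286      0.956    0.956
          rf    0.463  0.835      0.390      0.917    0.934
         knn    0.582  0.737      0.573      0.816    0.894
      greedy    0.311  0.926      0.286      0.956    0.956
stack_linear    0.309  0.927      0.281      0.957    0.957

lowest test RMSE: 0.281 (stack_linear)
acceptability (linear): q2_cv_gt_0.5=pass, r2_test_gt_0.6=pass, r2_vs_r2_0_lt_0.1=pass, k_in_0.85_1.15=pass
```

The synthetic property is a linear combination of compact-engine
descriptors plus Gaussian noise of sd 0.3, so an RMSE_CV around 0.31 means
the linear model has reached the noise floor; the stacking ensemble edges
out the best single model on the held-out 24 molecules (0.281 vs 0.286),
and all four acceptability criteria pass. `results.predict("new.csv")`
then standardises, describes, preprocesses and predicts new molecules with
the stored state; `results.save("model.joblib")` persists the bundle.

A CLI mirrors this flow: `qsarkit train`, `qsarkit predict`,
`qsarkit validate`, `qsarkit summarize` (compound×target matrix
completeness), `qsarkit fixture` (synthetic datasets).

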