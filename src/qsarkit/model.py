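"""High-level modelling objects.

:class:`QsarModel` is the front door for the whole workflow: construct it
from a table of molecules with a numeric property (or from a molecule file),
call :meth:`~QsarModel.fit`, and get back a :class:`QsarResults` carrying
the fitted bundles, cross-validation and test-set statistics, ensembles and
a ``summary()`` table. The functional modules underneath
(:mod:`~qsarkit.standardize`, :mod:`~qsarkit.descriptors`,
:mod:`~qsarkit.preprocess`, :mod:`~qsarkit.cv`, :mod:`~qsarkit.ensemble`,
:mod:`~qsarkit.validate`) remain usable on their own.

Example
-------
>>> from qsarkit import QsarModel, WorkflowConfig, synthetic
>>> table, truth = synthetic.make_qspr_fixture(synthetic.SyntheticSpec(seed=7))
>>> model = QsarModel.from_dataframe(table, property_column="property")
>>> results = model.fit(seed=7)
>>> print(results.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bundle import DescriptorConfig, ModelBundle, compute_descriptors, predict_external
from .cv import CVResult, FoldAssignment, cross_validate, fit_final, make_folds, split_set
from .descriptors import engine_version
from .ensemble import EnsembleWeights, StackModel, ensemble_predict, greedy_ensemble, stack_ensemble
from .errors import ConfigurationError, DataValidationError
from .preprocess import apply_preprocess, fit_preprocess
from .standardize import (
    MoleculeRecord,
    StandardizationConfig,
    kept,
    read_molecules,
    standardise_molecules,
)
from .validate import ObservedPredicted, ValidationReport, cv_metrics, test_metrics

#: default hyper-parameter grids per learner, deliberately small
DEFAULT_GRIDS: dict[str, dict] = {
    "linear": {},
    "elastic_net": {"alpha": [2.0**p for p in range(-8, 1, 2)], "l1_ratio": [0.2, 0.5, 0.8]},
    "rf": {"n_estimators": [100], "max_features": [0.33, 1.0]},
    "gbm": {"n_estimators": [100, 200], "max_depth": [2, 3]},
    "svm_radial": {"C": [2.0**p for p in range(-2, 5, 2)], "gamma": ["scale"]},
    "svm_linear": {"C": [2.0**p for p in range(-2, 5, 2)]},
    "kernel_ridge": {"alpha": [2.0**p for p in range(-6, 1, 2)]},
    "knn": {"n_neighbors": [3, 5, 7]},
}


@dataclass(frozen=True)
class WorkflowConfig:
    """Every knob of the end-to-end workflow, with field-standard defaults."""

    standardization: StandardizationConfig = field(default_factory=StandardizationConfig)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    train_fraction: float = 0.8  # |train| = round(fraction · n)
    split_method: str = "random"
    k_folds: int = 5
    fold_method: str = "random"
    freq_cut: float = 30.0
    unique_cut: float = 10.0
    corr_cutoff: float = 0.95
    learners: dict = field(default_factory=lambda: {"rf": None})  # name -> grid (None = default)

    def grids(self) -> dict[str, dict]:
        out = {}
        for name, grid in self.learners.items():
            out[name] = DEFAULT_GRIDS.get(name, {}) if grid is None else grid
        return out


@dataclass
class FittedLearner:
    """One base model's complete fit: CV outcome, final estimator, test report."""

    name: str
    cv: CVResult
    estimator: object
    test_predictions: np.ndarray
    report: ValidationReport
    bundle: ModelBundle


class QsarResults:
    """Estimates, uncertainties and diagnostics from a fitted workflow."""

    def __init__(
        self,
        config: WorkflowConfig,
        records: list[MoleculeRecord],
        train_idx: np.ndarray,
        test_idx: np.ndarray,
        y: np.ndarray,
        folds: FoldAssignment,
        learners: dict[str, FittedLearner],
        seed: int,
    ) -> None:
        self.config = config
        self.records = records
        self.train_idx = train_idx
        self.test_idx = test_idx
        self.y = y
        self.folds = folds
        self.learners = learners
        self.seed = seed
        self.ensembles: dict[str, dict] = {}

    # -- convenience views ---------------------------------------------------
    @property
    def y_train(self) -> np.ndarray:
        return self.y[self.train_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.y[self.test_idx]

    def oof_matrix(self) -> np.ndarray:
        """Out-of-fold predictions of every base model (rows = training samples)."""
        return np.column_stack([fl.cv.best_oof for fl in self.learners.values()])

    def test_matrix(self) -> np.ndarray:
        return np.column_stack([fl.test_predictions for fl in self.learners.values()])

    # -- ensembles -----------------------------------------------------------
    def add_greedy_ensemble(self, n_iter: int = 1000) -> EnsembleWeights:
        names = list(self.learners)
        ens = greedy_ensemble(self.oof_matrix(), self.y_train, n_iter=n_iter, model_names=names)
        self.ensembles["greedy"] = self._evaluate_ensemble("greedy", ens)
        return ens

    def add_stacking_ensemble(self, meta_learner: str = "linear", **kwargs) -> StackModel:
        names = list(self.learners)
        ens = stack_ensemble(
            self.oof_matrix(),
            self.y_train,
            meta_learner=meta_learner,
            folds=self.folds,
            model_names=names,
            seed=self.seed,
            **kwargs,
        )
        self.ensembles[f"stack_{meta_learner}"] = self._evaluate_ensemble(
            f"stack_{meta_learner}", ens
        )
        return ens

    def _evaluate_ensemble(self, label: str, ens) -> dict:
        oof_pred = ensemble_predict(ens, self.oof_matrix())
        test_pred = ensemble_predict(ens, self.test_matrix())
        op_cv = ObservedPredicted(
            y=self.y_train, y_hat=oof_pred, y_train_mean=float(self.y_train.mean())
        )
        q2, rmse_cv = cv_metrics(op_cv)
        op = ObservedPredicted.from_training(self.y_test, test_pred, self.y_train)
        report = test_metrics(op, q2_cv=q2)
        return {
            "ensemble": ens,
            "rmse_cv": rmse_cv,
            "q2_cv": q2,
            "test_predictions": test_pred,
            "report": report,
        }

    # -- output --------------------------------------------------------------
    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name, fl in self.learners.items():
            rows.append(
                {
                    "model": name,
                    "rmse_cv": fl.cv.mean_rmse(),
                    "r2_cv": fl.cv.mean_q2(),
                    "rmse_test": fl.report.rmse,
                    "r2_0_test": fl.report.r2_0,
                    "r2_test": fl.report.r2_test,
                }
            )
        for label, ev in self.ensembles.items():
            rows.append(
                {
                    "model": label,
                    "rmse_cv": ev["rmse_cv"],
                    "r2_cv": ev["q2_cv"],
                    "rmse_test": ev["report"].rmse,
                    "r2_0_test": ev["report"].r2_0,
                    "r2_test": ev["report"].r2_test,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_kept = len(self.y)
        lines = [
            "QSAR/QSPR workflow results",
            "==========================",
            f"molecules kept: {n_kept}  (train {len(self.train_idx)}, test {len(self.test_idx)})",
            f"folds: {self.folds.k} ({self.folds.method}), seed {self.seed}",
            f"descriptor engine: {engine_version()}",
            "",
            self.metrics_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        best = self.metrics_frame().sort_values("rmse_test").iloc[0]
        lines += ["", f"lowest test RMSE: {best['rmse_test']:.3f} ({best['model']})"]
        first = next(iter(self.learners.values()))
        if first.report.tropsha:
            flags = ", ".join(f"{k}={'pass' if v else 'FAIL'}" for k, v in first.report.tropsha.items())
            lines += [f"acceptability ({first.name}): {flags}"]
        return "\n".join(lines)

    def predict(self, molecules, learner: str | None = None, **kwargs) -> pd.DataFrame:
        """Predict an external molecule file/record list with one base model."""
        name = learner or next(iter(self.learners))
        return predict_external(self.learners[name].bundle, molecules, **kwargs)

    def save(self, path: str | Path, learner: str | None = None) -> None:
        name = learner or next(iter(self.learners))
        self.learners[name].bundle.save(path)


class QsarModel:
    """A property/bioactivity model specification bound to data.

    Construct from a DataFrame (``from_dataframe``), a molecule file
    (``from_file``) or a list of :class:`MoleculeRecord`; ``fit`` runs
    standardisation → descriptors → preprocessing → split → grid-search CV →
    final fits → test-set validation for every configured learner.
    """

    def __init__(self, records: Sequence[MoleculeRecord], config: WorkflowConfig | None = None):
        self.records = list(records)
        self.config = config or WorkflowConfig()
        if not self.records:
            raise DataValidationError("no molecule records supplied")

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        smiles_column: str = "smiles",
        property_column: str = "property",
        id_column: str = "id",
        config: WorkflowConfig | None = None,
    ) -> "QsarModel":
        if smiles_column not in table.columns:
            raise ConfigurationError(f"table lacks smiles column {smiles_column!r}")
        if property_column not in table.columns:
            raise ConfigurationError(f"table lacks property column {property_column!r}")
        records = [
            MoleculeRecord(
                id=str(row[id_column]) if id_column in table.columns else f"mol{i + 1}",
                smiles_raw=str(row[smiles_column]),
                property=float(row[property_column]),
            )
            for i, (_, row) in enumerate(table.iterrows())
        ]
        return cls(records, config)

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        format: str | None = None,
        property_column: str = "property",
        smiles_column: str = "smiles",
        config: WorkflowConfig | None = None,
    ) -> "QsarModel":
        records = read_molecules(
            path, format=format, property_column=property_column, smiles_column=smiles_column
        )
        return cls(records, config)

    def fit(self, seed: int = 0) -> QsarResults:
        cfg = self.config
        std = standardise_molecules(self.records, cfg.standardization)
        survivors = [r for r in kept(std) if r.property is not None]
        if len(survivors) < 10:
            raise DataValidationError(
                f"only {len(survivors)} standardised molecules with a property value"
            )
        y = np.array([r.property for r in survivors], dtype=float)
        X_all, basis = compute_descriptors(survivors, cfg.descriptors)

        train_idx, test_idx = split_set(
            y, fraction=cfg.train_fraction, method=cfg.split_method, seed=seed
        )
        X_train_raw = X_all.data.iloc[train_idx]
        X_test_raw = X_all.data.iloc[test_idx]
        X_train, state = fit_preprocess(
            X_train_raw,
            freq_cut=cfg.freq_cut,
            unique_cut=cfg.unique_cut,
            corr_cutoff=cfg.corr_cutoff,
        )
        X_test = apply_preprocess(state, X_test_raw)
        y_train, y_test = y[train_idx], y[test_idx]
        folds = make_folds(y_train, k=cfg.k_folds, method=cfg.fold_method, seed=seed)

        fitted: dict[str, FittedLearner] = {}
        for name, grid in cfg.grids().items():
            cvres = cross_validate(name, grid, X_train, y_train, folds, seed=seed)
            est = fit_final(name, cvres.best_params, X_train, y_train, seed=seed)
            test_pred = np.ravel(est.predict(X_test.to_numpy(dtype=float)))
            op = ObservedPredicted.from_training(y_test, test_pred, y_train)
            report = test_metrics(op, q2_cv=cvres.mean_q2())
            bundle = ModelBundle(
                standardization=cfg.standardization,
                descriptors=cfg.descriptors,
                basis=basis,
                preprocess=state,
                learner=name,
                best_params=cvres.best_params,
                estimator=est,
                metadata={
                    "n_train": len(train_idx),
                    "n_test": len(test_idx),
                    "seed": seed,
                    "k_folds": cfg.k_folds,
                    "fold_method": cfg.fold_method,
                    "engine_version": engine_version(),
                },
                y_train=y_train,
                oof_predictions=cvres.best_oof,
                folds=folds,
            )
            fitted[name] = FittedLearner(
                name=name,
                cv=cvres,
                estimator=est,
                test_predictions=test_pred,
                report=report,
                bundle=bundle,
            )
        return QsarResults(
            config=cfg,
            records=std,
            train_idx=train_idx,
            test_idx=test_idx,
            y=y,
            folds=folds,
            learners=fitted,
            seed=seed,
        )


def ensemble_from_bundles(
    bundles: Sequence[ModelBundle], method: str = "greedy", n_iter: int = 1000, **kwargs
):
    """Combine already-trained bundles that share a fold specification.

    Uses the out-of-fold predictions stored in each bundle; all bundles must
    carry identical fold assignments and training responses.
    """
    if not bundles:
        raise DataValidationError("no bundles supplied")
    first = bundles[0]
    for b in bundles[1:]:
        if b.folds is None or first.folds is None or b.folds.fold_of != first.folds.fold_of:
            raise DataValidationError("bundles do not share an identical fold composition")
        if not np.array_equal(b.y_train, first.y_train):
            raise DataValidationError("bundles were trained on different responses")
    P = np.column_stack([b.oof_predictions for b in bundles])
    names = [b.learner for b in bundles]
    if method == "greedy":
        return greedy_ensemble(P, first.y_train, n_iter=n_iter, model_names=names)
    return stack_ensemble(
        P, first.y_train, meta_learner=method, folds=first.folds, model_names=names, **kwargs
    )
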