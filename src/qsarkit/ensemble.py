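"""Model ensembles: greedy weight selection and stacking.

Both techniques consume the matrix P of cross-validated (out-of-fold)
predictions — rows are training samples, columns are base models sharing one
fold composition — so the combiner is tuned on predictions the base models
made for samples they did not see.

Greedy selection keeps an integer count per model, all starting at zero.
Each round, every model's count is provisionally incremented by one, the
counts are normalised into weights, and the RMSE of the weighted prediction
is evaluated; the best increment is accepted only if it strictly lowers the
current RMSE. After n rounds the counts are normalised into the final
non-negative weight vector summing to one. This is ensemble selection with
replacement; the RMSE trace is non-increasing by construction and the final
ensemble is never worse (on P) than the best single model.

Stacking instead fits a meta-learner on (P, y); when the meta-learner
exposes input importances, the relative contribution of each base model is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cv import FoldAssignment
from .errors import DataValidationError, DomainError
from .learners import fit_predict, input_importances, make_learner
from .validate import rmse


@dataclass
class EnsembleWeights:
    """Convex-combination weights from greedy selection."""

    model_names: list[str]
    weights: np.ndarray
    n_iterations: int
    rmse_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise DataValidationError("weights must be non-negative and sum to 1")
        self.weights = w


@dataclass
class StackModel:
    """A meta-learner fitted on base-model out-of-fold predictions."""

    model_names: list[str]
    meta_learner: str
    estimator: object
    importances: dict[str, float] | None = None


def _check_P_y(P, y) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    if P.ndim != 2 or P.shape[1] < 1:
        raise DataValidationError("P must be a 2-D matrix with >= 1 model column")
    if P.shape[0] != len(y):
        raise DataValidationError("P and y differ in sample count")
    return P, y


def greedy_ensemble(
    P, y, n_iter: int = 1000, model_names: list[str] | None = None
) -> EnsembleWeights:
    """Greedy RMSE-minimising ensemble selection over out-of-fold predictions.

    All base models must share an identical fold composition — the caller's
    duty, since P carries no fold information.
    """
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    P, y = _check_P_y(P, y)
    n_models = P.shape[1]
    names = model_names or [f"model_{j}" for j in range(n_models)]
    if len(names) != n_models:
        raise DataValidationError("model_names length does not match P columns")
    counts = np.zeros(n_models, dtype=int)
    current = np.inf
    trace: list[float] = []
    for _ in range(n_iter):
        best_m, best_rmse = -1, np.inf
        for m in range(n_models):
            counts[m] += 1
            cand = rmse(y, P @ (counts / counts.sum()))
            counts[m] -= 1
            if cand < best_rmse:  # strict: ties keep the lowest column index
                best_m, best_rmse = m, cand
        if best_rmse < current:
            counts[best_m] += 1
            current = best_rmse
            trace.append(current)
        else:
            break  # deterministic: further rounds would repeat the same no-op
    return EnsembleWeights(
        model_names=names,
        weights=counts / counts.sum(),
        n_iterations=n_iter,
        rmse_trace=trace,
    )


def stack_ensemble(
    P,
    y,
    meta_learner: str = "linear",
    folds: FoldAssignment | None = None,
    meta_grid: dict | None = None,
    seed: int | None = 0,
    model_names: list[str] | None = None,
) -> StackModel:
    """Fit a meta-learner on base-model out-of-fold predictions.

    With a ``meta_grid`` and ``folds``, the meta-learner's hyper-parameters
    are tuned by the same fold assignment the base models used; otherwise it
    is fitted directly with its defaults.
    """
    P, y = _check_P_y(P, y)
    names = model_names or [f"model_{j}" for j in range(P.shape[1])]
    params: dict = {}
    if meta_grid:
        if folds is None:
            raise DataValidationError("meta-learner tuning requires the shared fold assignment")
        from .cv import cross_validate  # local import to avoid a cycle at module load

        params = cross_validate(meta_learner, meta_grid, P, y, folds, seed=seed).best_params
    est = make_learner(meta_learner, params, seed)
    est.fit(P, y)
    imps = input_importances(est)
    importances = (
        {name: float(v) for name, v in zip(names, imps)} if imps is not None else None
    )
    return StackModel(
        model_names=names, meta_learner=meta_learner, estimator=est, importances=importances
    )


def ensemble_predict(ens: EnsembleWeights | StackModel, P_new) -> np.ndarray:
    """Apply an ensemble to base-model predictions on new data (columns must
    align with the ensemble's model order)."""
    P_new = np.asarray(P_new, dtype=float)
    if P_new.ndim != 2 or P_new.shape[1] != len(ens.model_names):
        raise DataValidationError(
            f"P_new must have {len(ens.model_names)} columns in the ensemble's model order"
        )
    if isinstance(ens, EnsembleWeights):
        return P_new @ ens.weights
    return np.ravel(ens.estimator.predict(P_new))
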