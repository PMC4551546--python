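"""Data splitting, fold construction, hyper-parameter grids and grid-search CV.

The training protocol: hold out a test fraction of the data, split the rest
into k folds (randomly or stratified on the response), and for every
hyper-parameter combination fit on k−1 folds and predict the held-out fold,
cycling through all folds. The combination with the lowest mean RMSE across
folds wins (configurable to q²); the final model is refitted on the whole
training set with those values. Out-of-fold predictions are retained per
combination because ensemble construction consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import DataValidationError, DomainError
from .learners import fit_predict, make_learner
from .validate import ObservedPredicted, cv_metrics

DEFAULT_STRATA = 5


@dataclass(frozen=True)
class FoldAssignment:
    """Fold id (1..k) for every training row."""

    fold_of: tuple[int, ...]
    k: int
    method: str
    seed: int

    def __post_init__(self) -> None:
        present = set(self.fold_of)
        if present != set(range(1, self.k + 1)):
            raise DataValidationError("every fold 1..k must be non-empty")

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) == fold)

    def complement(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) != fold)


def _quantile_bins(y: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = pd.Series(y).rank(method="first")
    return pd.qcut(ranks, q=min(n_bins, len(y)), labels=False).to_numpy()


def split_set(
    y, fraction: float = 0.8, method: str = "random", seed: int = 0, n_bins: int = DEFAULT_STRATA
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test indices with |train| = round(fraction·n).

    ``method="stratified"`` bins the response into quantile bins and samples
    proportionally from each, so both subsets cover the response range.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise DomainError("need at least 5 samples to split")
    if not 0.0 < fraction < 1.0:
        raise DomainError("fraction must be in (0, 1)")
    n_train = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    if method == "random":
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
        return train, test
    if method != "stratified":
        raise DomainError(f"unknown split method {method!r}")
    bins = _quantile_bins(y, n_bins)
    chosen: list[int] = []
    # proportional allocation: floor within each bin, then largest remainders
    order = sorted(set(bins))
    shuffled = {b: rng.permutation(np.flatnonzero(bins == b)) for b in order}
    quota = {b: fraction * len(shuffled[b]) for b in order}
    take = {b: int(np.floor(quota[b])) for b in order}
    short = n_train - sum(take.values())
    for b in sorted(order, key=lambda b: quota[b] - take[b], reverse=True)[: max(short, 0)]:
        take[b] += 1
    for b in order:
        chosen.extend(shuffled[b][: take[b]])
    train = np.sort(np.array(chosen, dtype=int))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def make_folds(
    y, k: int, method: str = "random", seed: int = 0, n_bins: int = DEFAULT_STRATA
) -> FoldAssignment:
    """Assign each training row to one of k folds, randomly or stratified on y."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2 or k > n:
        raise DomainError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    if method == "random":
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            fold_of[idx] = pos % k + 1
    elif method == "stratified":
        bins = _quantile_bins(y, n_bins)
        pos = 0
        for b in sorted(set(bins)):
            for idx in rng.permutation(np.flatnonzero(bins == b)):
                fold_of[idx] = pos % k + 1
                pos += 1
    else:
        raise DomainError(f"unknown fold method {method!r}")
    return FoldAssignment(fold_of=tuple(int(f) for f in fold_of), k=k, method=method, seed=seed)


def exp_grid(base: float, power_from: int, power_to: int) -> list[float]:
    """[base**p for p in power_from..power_to] — exponential hyper-parameter ladder."""
    if base <= 0:
        raise DomainError("base must be > 0")
    if power_from > power_to:
        raise DomainError("power_from must be <= power_to")
    return [float(base) ** p for p in range(power_from, power_to + 1)]


@dataclass
class CVResult:
    """Grid-search cross-validation outcome for one learner."""

    learner: str
    combos: list[dict]
    records: pd.DataFrame  # columns: combo, fold, rmse_cv, q2_cv
    oof: dict[int, np.ndarray]  # combo index -> out-of-fold predictions
    best_index: int
    best_params: dict
    folds: FoldAssignment

    @property
    def best_oof(self) -> np.ndarray:
        return self.oof[self.best_index]

    def mean_rmse(self, combo: int | None = None) -> float:
        combo = self.best_index if combo is None else combo
        sub = self.records[self.records["combo"] == combo]
        return float(sub["rmse_cv"].mean())

    def mean_q2(self, combo: int | None = None) -> float:
        combo = self.best_index if combo is None else combo
        sub = self.records[self.records["combo"] == combo]
        return float(sub["q2_cv"].mean())


def _expand_grid(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def cross_validate(
    learner: str,
    grid: dict,
    X,
    y,
    folds: FoldAssignment,
    seed: int | None = 0,
    metric: str = "rmse",
) -> CVResult:
    """Grid-search k-fold CV; returns per-fold metrics and out-of-fold predictions.

    ``metric`` selects the model-selection criterion: mean ``"rmse"`` across
    folds (minimised, the default) or mean ``"q2"`` (maximised). Ties keep
    the earliest combination in grid order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise DataValidationError("X and y differ in length")
    if len(y) != len(folds.fold_of):
        raise DataValidationError("fold assignment does not match data size")
    if metric not in ("rmse", "q2"):
        raise DomainError(f"unknown selection metric {metric!r}")
    combos = _expand_grid(grid)
    rows = []
    oof: dict[int, np.ndarray] = {}
    for ci, params in enumerate(combos):
        preds = np.full(len(y), np.nan)
        for f in range(1, folds.k + 1):
            fit_idx, pred_idx = folds.complement(f), folds.indices(f)
            est = make_learner(learner, params, seed)
            try:
                preds[pred_idx] = fit_predict(est, X[fit_idx], y[fit_idx], X[pred_idx])
            except Exception as exc:  # noqa: BLE001 - context added, then re-raised
                raise RuntimeError(
                    f"learner {learner!r} failed on combination {params} fold {f}: {exc}"
                ) from exc
            op = ObservedPredicted(
                y=y[pred_idx], y_hat=preds[pred_idx], y_train_mean=float(y[fit_idx].mean())
            )
            q2, rm = cv_metrics(op)
            rows.append({"combo": ci, "fold": f, "rmse_cv": rm, "q2_cv": q2})
        oof[ci] = preds
    records = pd.DataFrame(rows)
    means = records.groupby("combo")[["rmse_cv", "q2_cv"]].mean()
    if metric == "rmse":
        best = int(means["rmse_cv"].idxmin())  # idxmin keeps first on ties
    else:
        best = int(means["q2_cv"].idxmax())
    return CVResult(
        learner=learner,
        combos=combos,
        records=records,
        oof=oof,
        best_index=best,
        best_params=combos[best],
        folds=folds,
    )


def fit_final(learner: str, best_params: dict, X, y, seed: int | None = 0):
    """Refit the chosen learner on the whole training set."""
    est = make_learner(learner, best_params, seed)
    est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return est


def matrix_completeness(n_compounds: int, n_targets: int, n_datapoints: int) -> float:
    """Observed fraction of the compound×target bioactivity matrix, in percent
    (one decimal)."""
    if n_compounds < 1 or n_targets < 1 or n_datapoints < 0:
        raise DomainError("counts must be positive")
    if n_datapoints > n_compounds * n_targets:
        raise DomainError("more datapoints than matrix cells")
    return round(100.0 * n_datapoints / (n_compounds * n_targets), 1)


def aggregate_duplicates(
    table: pd.DataFrame,
    compound_col: str = "compound",
    target_col: str = "target",
    value_col: str = "value",
) -> pd.DataFrame:
    """Average the response over duplicated (compound, target) pairs."""
    for col in (compound_col, target_col, value_col):
        if col not in table.columns:
            raise DataValidationError(f"table lacks column {col!r}")
    grouped = (
        table.groupby([compound_col, target_col], sort=False)[value_col].mean().reset_index()
    )
    return grouped


def pcm_summary(
    table: pd.DataFrame,
    compound_col: str = "compound",
    target_col: str = "target",
    value_col: str = "value",
) -> dict:
    """Dataset summary for a compound×target activity table (after aggregation)."""
    agg = aggregate_duplicates(table, compound_col, target_col, value_col)
    n_compounds = agg[compound_col].nunique()
    n_targets = agg[target_col].nunique()
    n_points = len(agg)
    per_target = agg.groupby(target_col, sort=False).size().to_dict()
    return {
        "n_compounds": int(n_compounds),
        "n_targets": int(n_targets),
        "n_datapoints": int(n_points),
        "completeness_pct": matrix_completeness(n_compounds, n_targets, n_points),
        "datapoints_per_target": {str(k): int(v) for k, v in per_target.items()},
    }
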