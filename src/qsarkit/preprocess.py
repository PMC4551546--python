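"""Fit-and-replay descriptor preprocessing.

Descriptors enter learning algorithms on very different numeric scales and
often with redundant or empty columns, so before training they are passed
through a fixed pipeline: mean-imputation of missing values, removal of
near-zero-variance columns, removal of highly inter-correlated columns, then
centring to zero mean and scaling to unit (sample) variance. Every fitted
fact — imputation means, dropped columns, centres, scales — is recorded in a
:class:`PreprocessState` so the identical transformation can be replayed on
external molecules at prediction time: replaying on the training matrix
reproduces the fitted output bit for bit.

The near-zero-variance rule follows the classic caret filter: a column is
dropped iff the ratio of its most frequent value's count to the second most
frequent value's count exceeds ``freq_cut`` (infinite for constants) AND the
percentage of distinct values is at most ``unique_cut``. The correlation
filter repeatedly locates the most correlated pair and drops, from that pair,
the column with the larger mean absolute correlation to the remaining
columns (ties broken toward the larger column index).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError


@dataclass
class PreprocessState:
    """Everything needed to replay a fitted preprocessing pipeline."""

    impute_values: dict[str, float] = field(default_factory=dict)
    dropped_nzv: list[str] = field(default_factory=list)
    dropped_corr: list[str] = field(default_factory=list)
    centers: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    fitted_on: dict = field(default_factory=dict)  # {"n_rows": int, "columns": [...]}

    @property
    def surviving_columns(self) -> list[str]:
        dropped = set(self.dropped_nzv) | set(self.dropped_corr)
        return [c for c in self.fitted_on.get("columns", []) if c not in dropped]

    def to_json(self) -> str:
        return json.dumps(
            {
                "impute_values": self.impute_values,
                "dropped_nzv": self.dropped_nzv,
                "dropped_corr": self.dropped_corr,
                "centers": self.centers,
                "scales": self.scales,
                "fitted_on": self.fitted_on,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        return cls(**json.loads(text))


def impute_features(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replace missing entries by the column mean over non-missing entries."""
    all_missing = [c for c in X.columns if X[c].isna().all()]
    if all_missing:
        raise DataValidationError(f"columns with no observed values: {all_missing}")
    means = {c: float(X[c].mean()) for c in X.columns}
    return X.fillna(pd.Series(means)), means


def _freq_ratio(col: pd.Series) -> float:
    counts = col.value_counts()
    if len(counts) < 2:
        return np.inf
    return counts.iloc[0] / counts.iloc[1]


def remove_near_zero_variance(
    X: pd.DataFrame, freq_cut: float = 30.0, unique_cut: float = 10.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns whose value distribution carries almost no information.

    ``freq_cut`` is the most-frequent/second-most-frequent count ratio above
    which (strictly) a column is suspect; ``unique_cut`` the percentage of
    distinct values at or below which it is confirmed uninformative.
    """
    if X.isna().any().any():
        raise DataValidationError("impute before the near-zero-variance filter")
    n = len(X)
    dropped = []
    for c in X.columns:
        ratio = _freq_ratio(X[c])
        pct_unique = 100.0 * X[c].nunique() / n
        if ratio > freq_cut and pct_unique <= unique_cut:
            dropped.append(c)
    return X.drop(columns=dropped), dropped


def remove_highly_correlated(
    X: pd.DataFrame, cutoff: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns until no pair has |Pearson r| above ``cutoff``."""
    if X.isna().any().any():
        raise DataValidationError("impute before the correlation filter")
    if len(X) < 2:
        raise DataValidationError("correlation filter needs >= 2 rows")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise DataValidationError(
            f"zero-variance columns present (run the near-zero-variance filter first): {constant}"
        )
    corr = X.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(X.columns)))
    dropped_idx: list[int] = []
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= cutoff:
            break
        a_loc, b_loc = np.unravel_index(np.argmax(sub), sub.shape)
        # mean |r| of each pair member against every other remaining column
        mean_a = sub[a_loc].sum() / (len(alive) - 1)
        mean_b = sub[b_loc].sum() / (len(alive) - 1)
        if mean_a > mean_b:
            victim_loc = a_loc
        elif mean_b > mean_a:
            victim_loc = b_loc
        else:
            victim_loc = max(a_loc, b_loc)
        dropped_idx.append(alive.pop(victim_loc))
    dropped = [X.columns[i] for i in sorted(dropped_idx)]
    return X.drop(columns=dropped), dropped


def center_scale(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Centre each column to mean 0 and scale to sample standard deviation 1 (n−1)."""
    if X.isna().any().any():
        raise DataValidationError("impute before centring/scaling")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise DataValidationError(f"cannot scale constant columns: {constant}")
    centers = {c: float(X[c].mean()) for c in X.columns}
    scales = {c: float(X[c].std(ddof=1)) for c in X.columns}
    out = (X - pd.Series(centers)) / pd.Series(scales)
    return out, centers, scales


def fit_preprocess(
    X: pd.DataFrame,
    freq_cut: float = 30.0,
    unique_cut: float = 10.0,
    corr_cutoff: float = 0.95,
    nzv: bool = True,
    correlation: bool = True,
    scale: bool = True,
) -> tuple[pd.DataFrame, PreprocessState]:
    """Fit the full pipeline (impute → NZV → correlation → centre/scale).

    Returns the transformed training matrix and the replayable state. The
    returned matrix is produced by :func:`apply_preprocess` on the fitted
    state, which guarantees fit and replay share one code path.
    """
    state = PreprocessState(fitted_on={"n_rows": int(len(X)), "columns": list(X.columns)})
    work, state.impute_values = impute_features(X)
    if nzv:
        work, state.dropped_nzv = remove_near_zero_variance(work, freq_cut, unique_cut)
    if correlation:
        work, state.dropped_corr = remove_highly_correlated(work, corr_cutoff)
    if scale:
        _, state.centers, state.scales = center_scale(work)
    return apply_preprocess(state, X), state


def apply_preprocess(state: PreprocessState, X_new: pd.DataFrame) -> pd.DataFrame:
    """Replay a fitted pipeline on new data.

    Missing entries are imputed with the *training* means; training-time
    drops, centres and scales are applied verbatim. Extra columns are ignored
    with a warning; absent expected columns are an error.
    """
    expected = state.fitted_on["columns"]
    missing = [c for c in expected if c not in X_new.columns]
    if missing:
        raise DataValidationError(f"new data lacks expected columns: {missing[:10]}")
    extra = [c for c in X_new.columns if c not in set(expected)]
    if extra:
        warnings.warn(f"ignoring {len(extra)} columns not seen at fit time", stacklevel=2)
    work = X_new[expected].astype(float)
    work = work.fillna(pd.Series(state.impute_values))
    keep = [c for c in expected if c not in set(state.dropped_nzv) | set(state.dropped_corr)]
    work = work[keep]
    if state.centers:
        work = (work - pd.Series(state.centers)) / pd.Series(state.scales)
    return work


def preprocessing_report(state: PreprocessState) -> pd.DataFrame:
    """Dropped columns and the filter responsible, as a tidy table."""
    rows = [{"column": c, "reason": "near_zero_variance"} for c in state.dropped_nzv]
    rows += [{"column": c, "reason": "high_correlation"} for c in state.dropped_corr]
    return pd.DataFrame(rows, columns=["column", "reason"])
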