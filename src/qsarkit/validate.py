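"""Regression-model validation statistics and achievable-performance bounds.

Cross-validation metrics
    q²_CV = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ_tr)²       (ȳ_tr = training-set mean)
    RMSE  = √( Σ(yᵢ−ŷᵢ)² / N )

Test-set metrics come in three explained-variance flavours that differ only
in the reference variance:
    Q²₁ uses Σ(y_j−ȳ_tr)²  (training mean),
    Q²₂ uses Σ(y_j−ȳ_test)² (test mean),
    Q²₃ uses PRESS/N_test over SS_tr/N_tr (training variance per case);
plus RMSE, the Pearson correlation R between observed and predicted, and
R²₀, the squared coefficient of determination of the least-squares
regression *through the origin* of observed on predicted: with slope
k = Σ y·ŷ / Σ ŷ², the origin-constrained predictions are ŷ^r0 = k·ŷ and
R²₀ = 1 − Σ(y−ŷ^r0)²/Σ(y−ȳ_test)².

The Tropsha–Golbraikh acceptability criteria combine these:
q²_CV > 0.5, R²_test > 0.6, (R²_test−R²₀)/R²_test < 0.1, 0.85 ≤ k ≤ 1.15.

When the experimental uncertainty of the response is known, the metrics can
be put in context by Monte-Carlo bounds: the *maximum* achievable
performance draws test-sized samples from the response pool and scores them
against themselves plus Gaussian noise of the stated uncertainty; the
*minimum* additionally permutes the sample first, destroying all signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError, DegenerateResponseError, DomainError


@dataclass
class ObservedPredicted:
    """Observed/predicted pairs plus the training-set reference statistics."""

    y: np.ndarray
    y_hat: np.ndarray
    y_train_mean: float | None = None
    n_train: int | None = None
    ss_train: float | None = None  # Σ(y_tr − ȳ_tr)², needed for Q²₃

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if self.y.shape != self.y_hat.shape or self.y.ndim != 1:
            raise DataValidationError("y and y_hat must be 1-D vectors of equal length")
        if len(self.y) < 2:
            raise DataValidationError("need at least two observations")

    @classmethod
    def from_training(cls, y, y_hat, y_train) -> "ObservedPredicted":
        y_train = np.asarray(y_train, dtype=float)
        m = float(y_train.mean())
        return cls(
            y=y,
            y_hat=y_hat,
            y_train_mean=m,
            n_train=len(y_train),
            ss_train=float(((y_train - m) ** 2).sum()),
        )


@dataclass
class ValidationReport:
    """All test-set statistics plus the Tropsha–Golbraikh pass flags."""

    rmse: float
    r_test: float
    q2_1: float | None
    q2_2: float
    q2_3: float | None
    k_slope: float
    r2_0: float
    q2_cv: float | None = None
    tropsha: dict[str, bool] = field(default_factory=dict)

    @property
    def r2_test(self) -> float:
        return self.r_test**2

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "r_test": self.r_test,
            "r2_test": self.r2_test,
            "q2_1": self.q2_1,
            "q2_2": self.q2_2,
            "q2_3": self.q2_3,
            "k_slope": self.k_slope,
            "r2_0": self.r2_0,
            "q2_cv": self.q2_cv,
            "tropsha": dict(self.tropsha),
        }


def rmse(y, y_hat) -> float:
    """Root mean squared error √(Σ(yᵢ−ŷᵢ)²/N)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.sqrt(((y - y_hat) ** 2).sum() / len(y)))


def cv_metrics(op: ObservedPredicted) -> tuple[float, float]:
    """(q²_CV, RMSE_CV) for out-of-fold predictions against the training mean."""
    if op.y_train_mean is None:
        raise DataValidationError("cv_metrics needs y_train_mean")
    denom = float(((op.y - op.y_train_mean) ** 2).sum())
    if denom == 0.0:
        raise DegenerateResponseError("observations identical to the training mean")
    q2 = 1.0 - float(((op.y - op.y_hat) ** 2).sum()) / denom
    return q2, rmse(op.y, op.y_hat)


def test_metrics(op: ObservedPredicted, q2_cv: float | None = None) -> ValidationReport:
    """Full test-set validation report; Q²₁/Q²₃ require the training references."""
    y, y_hat = op.y, op.y_hat
    press = float(((y - y_hat) ** 2).sum())
    ss_test = float(((y - y.mean()) ** 2).sum())
    if ss_test == 0.0 or float(((y_hat - y_hat.mean()) ** 2).sum()) == 0.0:
        raise DegenerateResponseError("zero variance in y or y_hat: R undefined")
    sum_yhat_sq = float((y_hat**2).sum())
    if sum_yhat_sq == 0.0:
        raise DegenerateResponseError("all predictions zero: origin slope undefined")

    q2_1 = None
    if op.y_train_mean is not None:
        denom1 = float(((y - op.y_train_mean) ** 2).sum())
        if denom1 == 0.0:
            raise DegenerateResponseError("test observations identical to training mean")
        q2_1 = 1.0 - press / denom1
    q2_2 = 1.0 - press / ss_test
    q2_3 = None
    if op.ss_train is not None and op.n_train:
        var_train = op.ss_train / op.n_train
        if var_train == 0.0:
            raise DegenerateResponseError("zero training variance: Q²₃ undefined")
        q2_3 = 1.0 - (press / len(y)) / var_train

    r = float(np.corrcoef(y, y_hat)[0, 1])
    k = float((y * y_hat).sum() / sum_yhat_sq)
    r2_0 = 1.0 - float(((y - k * y_hat) ** 2).sum()) / ss_test

    report = ValidationReport(
        rmse=rmse(y, y_hat),
        r_test=r,
        q2_1=q2_1,
        q2_2=q2_2,
        q2_3=q2_3,
        k_slope=k,
        r2_0=r2_0,
        q2_cv=q2_cv,
    )
    if q2_cv is not None:
        report.tropsha = tropsha_criteria(report, q2_cv)
    return report


def tropsha_criteria(report: ValidationReport, q2_cv: float) -> dict[str, bool]:
    """The four model-acceptability checks of Tropsha and Golbraikh."""
    r2 = report.r2_test
    return {
        "q2_cv_gt_0.5": q2_cv > 0.5,
        "r2_test_gt_0.6": r2 > 0.6,
        "r2_vs_r2_0_lt_0.1": (r2 - report.r2_0) / r2 < 0.1,
        "k_in_0.85_1.15": 0.85 <= report.k_slope <= 1.15,
    }


@dataclass
class PerformanceBounds:
    """Monte-Carlo distributions of the best (or worst) attainable metrics."""

    direction: str  # "max" or "min"
    noise_sd: float
    n_reps: int
    seed: int
    distributions: dict[str, np.ndarray] = field(default_factory=dict)

    def means(self) -> dict[str, float]:
        return {m: float(v.mean()) for m, v in self.distributions.items()}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.distributions)


_BOUND_METRICS = ("r2_0", "r", "q2_1", "q2_2", "q2_3", "rmse")


def _bounds(
    y_pool, noise_sd: float, n_test: int, n_reps: int, seed: int, permute: bool
) -> PerformanceBounds:
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    y_pool = np.asarray(y_pool, dtype=float)
    if n_test < 2:
        raise DomainError("n_test must be >= 2")
    rng = np.random.default_rng(seed)
    pool_mean = float(y_pool.mean())
    ss_pool = float(((y_pool - pool_mean) ** 2).sum())
    dists: dict[str, list[float]] = {m: [] for m in _BOUND_METRICS}
    for _ in range(n_reps):
        replace = n_test > len(y_pool)
        S = rng.choice(y_pool, size=n_test, replace=replace)
        S_noise = S + rng.normal(0.0, noise_sd, size=n_test) if noise_sd > 0 else S.copy()
        observed = rng.permutation(S) if permute else S
        press = float(((observed - S_noise) ** 2).sum())
        ss_obs = float(((observed - observed.mean()) ** 2).sum())
        sum_sq = float((S_noise**2).sum())
        k = (observed * S_noise).sum() / sum_sq if sum_sq > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            sd_o, sd_p = observed.std(), S_noise.std()
            r = (
                float(np.corrcoef(observed, S_noise)[0, 1])
                if sd_o > 0 and sd_p > 0
                else (1.0 if press == 0.0 else np.nan)
            )
        dists["rmse"].append(np.sqrt(press / n_test))
        dists["r"].append(r)
        dists["r2_0"].append(
            1.0 - float(((observed - k * S_noise) ** 2).sum()) / ss_obs if ss_obs > 0 else np.nan
        )
        dists["q2_1"].append(1.0 - press / float(((observed - pool_mean) ** 2).sum()))
        dists["q2_2"].append(1.0 - press / ss_obs if ss_obs > 0 else np.nan)
        dists["q2_3"].append(1.0 - (press / n_test) / (ss_pool / len(y_pool)))
    return PerformanceBounds(
        direction="min" if permute else "max",
        noise_sd=noise_sd,
        n_reps=n_reps,
        seed=seed,
        distributions={m: np.array(v) for m, v in dists.items()},
    )


def max_performance(
    y_pool, noise_sd: float, n_test: int, n_reps: int = 1000, seed: int = 0
) -> PerformanceBounds:
    """Best-case metric distributions given only experimental noise.

    Each repetition draws a test-sized sample S from the response pool
    (without replacement when it fits, with replacement otherwise), adds
    Gaussian noise of sd ``noise_sd``, and scores S against its noisy copy.
    """
    return _bounds(y_pool, noise_sd, n_test, n_reps, seed, permute=False)


def min_performance(
    y_pool, noise_sd: float, n_test: int, n_reps: int = 1000, seed: int = 0
) -> PerformanceBounds:
    """Worst-case distributions: as :func:`max_performance` but the observed
    sample is randomly permuted first, so predictions carry no signal."""
    return _bounds(y_pool, noise_sd, n_test, n_reps, seed, permute=True)
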