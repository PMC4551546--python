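"""Named regression learners.

A thin registry over scikit-learn regressors so the cross-validation,
ensemble and bundle machinery can refer to learners by name and
hyper-parameters by plain dicts. Seeds are injected into every stochastic
estimator; deterministic estimators ignore them.
"""

from __future__ import annotations

from typing import Any, Callable

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .errors import ConfigurationError

_FACTORIES: dict[str, Callable[[dict, int | None], Any]] = {
    "linear": lambda p, s: LinearRegression(**p),
    "elastic_net": lambda p, s: ElasticNet(random_state=s, max_iter=10000, **p),
    "rf": lambda p, s: RandomForestRegressor(random_state=s, **p),
    "gbm": lambda p, s: GradientBoostingRegressor(random_state=s, **p),
    "svm_radial": lambda p, s: SVR(kernel="rbf", **p),
    "svm_linear": lambda p, s: SVR(kernel="linear", **p),
    "kernel_ridge": lambda p, s: KernelRidge(**p),
    "knn": lambda p, s: KNeighborsRegressor(**p),
}

#: learners whose fitted attributes expose per-input importances
_IMPORTANCE_ATTRS = ("feature_importances_", "coef_")


def available_learners() -> list[str]:
    return sorted(_FACTORIES)


def make_learner(name: str, params: dict | None = None, seed: int | None = None):
    """Instantiate a registered learner with the given hyper-parameters."""
    if name not in _FACTORIES:
        raise ConfigurationError(f"unknown learner {name!r}; known: {available_learners()}")
    return _FACTORIES[name](dict(params or {}), seed)


def register_learner(name: str, factory: Callable[[dict, int | None], Any]) -> None:
    """Add a learner factory ``(params, seed) -> estimator`` under ``name``."""
    _FACTORIES[name] = factory


def fit_predict(estimator, X_fit, y_fit, X_pred) -> np.ndarray:
    estimator.fit(np.asarray(X_fit, dtype=float), np.asarray(y_fit, dtype=float))
    return np.ravel(estimator.predict(np.asarray(X_pred, dtype=float)))


def input_importances(estimator) -> np.ndarray | None:
    """Per-input importance scores if the fitted estimator exposes any."""
    for attr in _IMPORTANCE_ATTRS:
        if hasattr(estimator, attr):
            return np.abs(np.ravel(getattr(estimator, attr)))
    return None
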