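"""Model bundles: everything external prediction needs, in one artifact.

A trained model is only useful for new molecules if the *exact* training-time
processing can be replayed: the same standardisation options, the same
descriptor engine and parameters (including the unhashed-fingerprint basis),
the same preprocessing state, and the fitted learner. A
:class:`ModelBundle` packages all of that, plus the out-of-fold predictions
and fold assignment needed to combine several bundles into an ensemble
afterwards. Predicting the training file through a bundle reproduces the
in-sample predictions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .cv import FoldAssignment
from .descriptors import (
    DescriptorMatrix,
    FingerprintBasis,
    build_fingerprint_basis,
    compute_morgan_hashed,
    compute_morgan_unhashed,
    compute_physchem,
    concat_descriptors,
    engine_version,
)
from .errors import ConfigurationError
from .preprocess import PreprocessState, apply_preprocess
from .standardize import (
    MoleculeRecord,
    StandardizationConfig,
    kept,
    read_molecules,
    standardise_molecules,
)


@dataclass(frozen=True)
class DescriptorConfig:
    """Which descriptor blocks to compute and with what parameters.

    ``physchem`` names an engine (or None); ``morgan_hashed`` is
    ``{"radius": r, "n_bits": b, "mode": "binary"|"count"}`` or None;
    ``morgan_unhashed`` is ``{"radius": r, "mode": ...}`` or None — its basis
    is fixed on the training set.
    """

    physchem: str | None = "rdkit"
    morgan_hashed: dict | None = None
    morgan_unhashed: dict | None = None

    def __post_init__(self) -> None:
        if self.physchem is None and self.morgan_hashed is None and self.morgan_unhashed is None:
            raise ConfigurationError("at least one descriptor block is required")


def compute_descriptors(
    records: Sequence[MoleculeRecord],
    config: DescriptorConfig,
    basis: FingerprintBasis | None = None,
) -> tuple[DescriptorMatrix, FingerprintBasis | None]:
    """Compute the configured descriptor blocks for standardised records.

    When unhashed fingerprints are requested and no ``basis`` is supplied,
    the basis is built from ``records`` (training-set behaviour); passing the
    stored basis replays the training-time mapping on new molecules.
    """
    blocks = []
    if config.physchem is not None:
        blocks.append(compute_physchem(records, config.physchem))
    if config.morgan_hashed is not None:
        blocks.append(compute_morgan_hashed(records, **config.morgan_hashed))
    if config.morgan_unhashed is not None:
        opts = dict(config.morgan_unhashed)
        radius = opts.pop("radius", 2)
        if basis is None:
            basis = build_fingerprint_basis(records, radius)
        elif basis.radius != radius:
            raise ConfigurationError("stored basis radius differs from requested radius")
        blocks.append(compute_morgan_unhashed(records, basis, **opts))
    return concat_descriptors(*blocks), basis


@dataclass
class ModelBundle:
    """A self-contained trained model, replayable on external molecules."""

    standardization: StandardizationConfig
    descriptors: DescriptorConfig
    basis: FingerprintBasis | None
    preprocess: PreprocessState
    learner: str
    best_params: dict
    estimator: object
    metadata: dict = field(default_factory=dict)
    # retained for ensemble building over several bundles
    y_train: np.ndarray | None = None
    oof_predictions: np.ndarray | None = None
    folds: FoldAssignment | None = None

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        obj = joblib.load(Path(path))
        if not isinstance(obj, cls):
            raise ConfigurationError(f"{path} is not a qsarkit model bundle")
        return obj


def _predict_records(bundle: ModelBundle, records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    stored = bundle.metadata.get("engine_version")
    if stored is not None and stored != engine_version():
        raise ConfigurationError(
            f"descriptor engine version mismatch: bundle built with {stored}, "
            f"running {engine_version()}"
        )
    std = standardise_molecules(records, bundle.standardization)
    rows = pd.DataFrame({"id": [r.id for r in std], "status": [r.status for r in std]})
    rows["prediction"] = np.nan
    survivors = kept(std)
    if survivors:
        X, _ = compute_descriptors(survivors, bundle.descriptors, basis=bundle.basis)
        Xp = apply_preprocess(bundle.preprocess, X.data)
        preds = np.ravel(bundle.estimator.predict(Xp.to_numpy(dtype=float)))
        pred_of = dict(zip([r.id for r in survivors], preds))
        rows["prediction"] = [pred_of.get(i, np.nan) for i in rows["id"]]
    return rows


def predict_external(
    bundle: ModelBundle,
    molecules: str | Path | Sequence[MoleculeRecord],
    format: str | None = None,
    property_column: str | None = None,
    smiles_column: str = "smiles",
) -> pd.DataFrame:
    """Standardise, describe, preprocess and predict an external molecule set.

    Molecules removed by standardisation get their removal status and no
    prediction. Returns a table (id, status, prediction).
    """
    if isinstance(molecules, (str, Path)):
        records = read_molecules(
            molecules, format=format, property_column=property_column, smiles_column=smiles_column
        )
    else:
        records = list(molecules)
    return _predict_records(bundle, records)
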