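"""Molecular descriptors: physicochemical sets and Morgan circular fingerprints.

Two fingerprint flavours are provided. *Hashed* fingerprints fold every
atom-environment identifier into a fixed number of bits, binary or
count-valued. *Unhashed* (keyed) fingerprints give each substructure observed
in the training set its own column: a :class:`FingerprintBasis` is built once
on the training molecules as the sorted union of Morgan environment
identifiers up to the chosen radius, and every later matrix — including for
external compounds — is expressed on that fixed basis, so a model's
coefficients stay attached to identifiable substructures. Substructures of a
new compound that are absent from the basis are dropped (its row is simply
zero there), which is what allows prediction for molecules containing
chemistry the training set never saw.

Note the diameter/radius convention: a substructure of maximal diameter 4
bonds corresponds to Morgan radius 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors
from rdkit.Chem import rdFingerprintGenerator

from .errors import ConfigurationError, DomainError
from .standardize import HALOGENS, MoleculeRecord


@dataclass
class DescriptorMatrix:
    """Named descriptor columns for a set of samples, with provenance."""

    data: pd.DataFrame  # index = row ids, columns = descriptor names
    engine: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ConfigurationError("duplicate descriptor column names")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="id")


@dataclass(frozen=True)
class FingerprintBasis:
    """Ordered substructure identifiers fixed on a training set."""

    radius: int
    substructure_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = self.substructure_ids
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ConfigurationError("substructure_ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.substructure_ids)

    def to_json(self) -> str:
        return json.dumps({"radius": self.radius, "substructure_ids": list(self.substructure_ids)})

    @classmethod
    def from_json(cls, text: str) -> "FingerprintBasis":
        obj = json.loads(text)
        return cls(radius=obj["radius"], substructure_ids=tuple(obj["substructure_ids"]))


def _mols(records: Sequence[MoleculeRecord]) -> tuple[list[str], list[Chem.Mol]]:
    ids, mols = [], []
    for rec in records:
        if rec.smiles_std is None:
            raise ConfigurationError(f"record {rec.id!r} is not standardised")
        ids.append(rec.id)
        mols.append(Chem.MolFromSmiles(rec.smiles_std))
    return ids, mols


# --- physicochemical engines -------------------------------------------------

def _rdkit_full(mol: Chem.Mol) -> dict[str, float]:
    return RDDescriptors.CalcMolDescriptors(mol, missingVal=np.nan)


_MINIMAL_FUNCS: dict[str, Callable[[Chem.Mol], float]] = {
    "heavy_atom_count": lambda m: float(m.GetNumHeavyAtoms()),
    "mol_weight": RDDescriptors.MolWt,
    "ring_count": RDDescriptors.RingCount,
    "aromatic_ring_count": lambda m: float(RDDescriptors.NumAromaticRings(m)),
    "rotatable_bonds": lambda m: float(RDDescriptors.NumRotatableBonds(m)),
    "hbond_donors": lambda m: float(RDDescriptors.NumHDonors(m)),
    "hbond_acceptors": lambda m: float(RDDescriptors.NumHAcceptors(m)),
    "tpsa": RDDescriptors.TPSA,
    "logp": RDDescriptors.MolLogP,
    "n_count": lambda m: float(sum(1 for a in m.GetAtoms() if a.GetSymbol() == "N")),
    "o_count": lambda m: float(sum(1 for a in m.GetAtoms() if a.GetSymbol() == "O")),
    **{
        f"{el.lower()}_count": (
            lambda m, el=el: float(sum(1 for a in m.GetAtoms() if a.GetSymbol() == el))
        )
        for el in HALOGENS
    },
}


def _rdkit_minimal(mol: Chem.Mol) -> dict[str, float]:
    return {name: f(mol) for name, f in _MINIMAL_FUNCS.items()}


#: registry of physicochemical descriptor engines; each maps Mol -> {name: value}
PHYSCHEM_ENGINES: dict[str, Callable[[Chem.Mol], Mapping[str, float]]] = {
    "rdkit": _rdkit_full,
    "rdkit_minimal": _rdkit_minimal,
}


def engine_version() -> str:
    return rdkit.__version__


def compute_physchem(
    records: Sequence[MoleculeRecord], descriptor_set: str = "rdkit"
) -> DescriptorMatrix:
    """One row of 1D/2D physicochemical descriptors per standardised record.

    Individual descriptor failures become NaN, to be imputed downstream.
    ``descriptor_set`` names an engine in :data:`PHYSCHEM_ENGINES`:
    ``"rdkit"`` is the host toolkit's full 2D list (~210 columns),
    ``"rdkit_minimal"`` a compact count/property set for cheap models.
    """
    if descriptor_set not in PHYSCHEM_ENGINES:
        raise ConfigurationError(
            f"unknown descriptor_set {descriptor_set!r}; known: {sorted(PHYSCHEM_ENGINES)}"
        )
    ids, mols = _mols(records)
    engine = PHYSCHEM_ENGINES[descriptor_set]
    rows = [dict(engine(mol)) for mol in mols]
    data = pd.DataFrame(rows, index=pd.Index(ids, name="id"), dtype=float)
    return DescriptorMatrix(
        data=data,
        engine=descriptor_set,
        parameters={"engine_version": engine_version()},
    )


# --- Morgan fingerprints -----------------------------------------------------

def _morgan_generator(radius: int, n_bits: int | None = None):
    if radius < 0:
        raise DomainError("radius must be >= 0")
    kwargs = {"radius": radius}
    if n_bits is not None:
        kwargs["fpSize"] = n_bits
    return rdFingerprintGenerator.GetMorganGenerator(**kwargs)


def compute_morgan_hashed(
    records: Sequence[MoleculeRecord],
    radius: int = 2,
    n_bits: int = 512,
    mode: str = "binary",
) -> DescriptorMatrix:
    """Hashed Morgan fingerprints: environment ids folded into ``n_bits`` columns."""
    if n_bits < 1:
        raise DomainError("n_bits must be >= 1")
    if mode not in ("binary", "count"):
        raise ConfigurationError(f"mode must be 'binary' or 'count', got {mode!r}")
    gen = _morgan_generator(radius, n_bits)
    ids, mols = _mols(records)
    X = np.zeros((len(mols), n_bits), dtype=float)
    for i, mol in enumerate(mols):
        if mode == "binary":
            for bit in gen.GetFingerprint(mol).GetOnBits():
                X[i, bit] = 1.0
        else:
            for bit, count in gen.GetCountFingerprint(mol).GetNonzeroElements().items():
                X[i, bit] = float(count)
    cols = [f"morgan_{radius}_{b}" for b in range(n_bits)]
    data = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=cols)
    return DescriptorMatrix(
        data=data,
        engine="morgan_hashed",
        parameters={
            "radius": radius,
            "n_bits": n_bits,
            "mode": mode,
            "engine_version": engine_version(),
        },
    )


def _sparse_counts(mol: Chem.Mol, radius: int) -> dict[int, int]:
    gen = _morgan_generator(radius)
    return dict(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def build_fingerprint_basis(
    records: Sequence[MoleculeRecord], radius: int = 2
) -> FingerprintBasis:
    """Sorted union of all Morgan environment ids (radius 0..``radius``) in the set."""
    if len(records) == 0:
        raise DomainError("cannot build a fingerprint basis from an empty set")
    _, mols = _mols(records)
    ids: set[int] = set()
    for mol in mols:
        ids.update(_sparse_counts(mol, radius))
    return FingerprintBasis(radius=radius, substructure_ids=tuple(sorted(ids)))


def compute_morgan_unhashed(
    records: Sequence[MoleculeRecord],
    basis: FingerprintBasis,
    mode: str = "binary",
) -> DescriptorMatrix:
    """Keyed Morgan fingerprints on a fixed training-set basis.

    Columns are ordered as ``basis.substructure_ids``; substructures of a
    record that are not in the basis are silently dropped.
    """
    if len(basis) == 0:
        raise DomainError("fingerprint basis is empty")
    if mode not in ("binary", "count"):
        raise ConfigurationError(f"mode must be 'binary' or 'count', got {mode!r}")
    col_of = {sid: j for j, sid in enumerate(basis.substructure_ids)}
    ids, mols = _mols(records)
    X = np.zeros((len(mols), len(basis)), dtype=float)
    for i, mol in enumerate(mols):
        for sid, count in _sparse_counts(mol, basis.radius).items():
            j = col_of.get(sid)
            if j is not None:
                X[i, j] = 1.0 if mode == "binary" else float(count)
    cols = [f"sub_{sid}" for sid in basis.substructure_ids]
    data = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=cols)
    return DescriptorMatrix(
        data=data,
        engine="morgan_unhashed",
        parameters={
            "radius": basis.radius,
            "mode": mode,
            "basis_size": len(basis),
            "engine_version": engine_version(),
        },
    )


def concat_descriptors(*matrices: DescriptorMatrix) -> DescriptorMatrix:
    """Column-concatenate descriptor blocks sharing the same row ids."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.row_ids != first.row_ids:
            raise ConfigurationError("descriptor blocks have mismatched row ids")
    data = pd.concat([m.data for m in matrices], axis=1)
    return DescriptorMatrix(
        data=data,
        engine="+".join(m.engine for m in matrices),
        parameters={m.engine: m.parameters for m in matrices},
    )
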