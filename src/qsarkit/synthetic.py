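"""Deterministic synthetic fixtures for QSPR and PCM pipelines.

The generator enumerates small, stereochemistry-free organic molecules
(alkanes and their alcohol/amine/halide/acid/nitrile derivatives, simple
benzenes and pyridines) whose SMILES are parseable by construction, and
assigns each a property as a linear combination of cheap computed
descriptors plus Gaussian noise. Because the property is linear in columns
of the compact descriptor engine, a noise-free fixture is exactly
recoverable by a linear model run through the full pipeline — which is what
makes end-to-end correctness testable to numerical precision. Known
tautomer pairs can be injected to exercise standardisation convergence.

The PCM fixture adds synthetic aligned target sequences and builds an
activity as compound term + target term + interaction + noise, retaining a
chosen fraction of the compound×target matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .descriptors import _MINIMAL_FUNCS
from .errors import ConfigurationError
from .protein import GAP, AlignedSequenceSet
from .scales import AMINO_ACIDS, Z5

#: tautomer pairs that standard InChI collapses (N/O/S mobile hydrogens only;
#: keto-enol pairs are intentionally absent — their proton sits on carbon)
TAUTOMER_PAIRS: list[tuple[str, str]] = [
    ("O=c1cccc[nH]1", "Oc1ccccn1"),       # 2-pyridone / 2-hydroxypyridine
    ("O=c1cc[nH]cc1", "Oc1ccncc1"),       # 4-pyridone / 4-hydroxypyridine
    ("S=c1cccc[nH]1", "Sc1ccccn1"),       # 2-thiopyridone / 2-mercaptopyridine
    ("Cc1c[nH]cn1", "Cc1cnc[nH]1"),       # 4- / 5-methylimidazole
    ("O=c1nccc[nH]1", "Oc1ncccn1"),       # 2-pyrimidinone / 2-hydroxypyrimidine
    ("CC(N)=O", "CC(=N)O"),               # acetamide / acetimidic acid
]

DEFAULT_COEFFICIENTS = {
    "heavy_atom_count": 0.35,
    "cl_count": -0.9,
    "ring_count": 0.7,
    "hbond_donors": 0.5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a synthetic dataset."""

    n_molecules: int = 200
    seed: int = 0
    noise_sd: float = 0.1
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    include_tautomer_pairs: bool = False
    pcm: dict | None = None  # {"n_targets": int, "completeness": fraction}

    def __post_init__(self) -> None:
        if self.n_molecules < 10:
            raise ConfigurationError("n_molecules must be >= 10")
        if self.pcm is not None:
            c = self.pcm.get("completeness", 1.0)
            if not 0.0 < c <= 1.0:
                raise ConfigurationError("completeness must be in (0, 1]")
        unknown = [c for c in self.coefficients if c not in _MINIMAL_FUNCS]
        if unknown:
            raise ConfigurationError(f"coefficients name unknown descriptors: {unknown}")


def enumerate_molecules(n: int) -> list[str]:
    """The first ``n`` canonical SMILES of a fixed, duplicate-free enumeration."""
    chains = ["C" * i for i in range(1, 13)]
    suffixes = ["", "O", "N", "Cl", "F", "Br", "OC", "C(=O)O", "C#N", "C=C", "S"]
    rings = ["c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccc(O)cc1", "c1ccc(Cl)cc1", "c1ccc(N)cc1"]
    raw: list[str] = []
    raw.extend(rings)
    for chain in chains:
        for suf in suffixes:
            raw.append(chain + suf)
    for chain in chains[:6]:
        for ring in rings:
            raw.append(chain + ring)
    for chain in chains:
        raw.append("OC" + chain + "O")       # diols
        raw.append("ClC" + chain + "Cl")     # dichlorides
        raw.append("NC" + chain + "C(=O)O")  # amino acids (achiral backbone)
    seen, out = set(), []
    for smi in raw:
        mol = Chem.MolFromSmiles(smi)
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
    if n > len(out):
        raise ConfigurationError(
            f"enumeration provides only {len(out)} distinct molecules (asked for {n})"
        )
    return out[:n]


def _true_property(smiles: str, coefficients: dict) -> float:
    mol = Chem.MolFromSmiles(smiles)
    return float(sum(coef * _MINIMAL_FUNCS[name](mol) for name, coef in coefficients.items()))


def make_qspr_fixture(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Molecule table (id, smiles, property) plus the generating coefficients.

    Fully reproducible from ``spec.seed``; the returned ground truth maps
    compact-engine descriptor names to their linear coefficients.
    """
    rng = np.random.default_rng(spec.seed)
    smiles = enumerate_molecules(spec.n_molecules)
    if spec.include_tautomer_pairs:
        for a, b in TAUTOMER_PAIRS:
            smiles.extend([a, b])
    rows = []
    for i, smi in enumerate(smiles):
        y = _true_property(smi, spec.coefficients)
        if spec.noise_sd > 0:
            y += rng.normal(0.0, spec.noise_sd)
        rows.append({"id": f"syn{i + 1}", "smiles": smi, "property": y})
    return pd.DataFrame(rows), dict(spec.coefficients)


def write_qspr_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10f")


# --- PCM ---------------------------------------------------------------------

def _synthetic_alignment(n_targets: int, length: int, rng: np.random.Generator) -> AlignedSequenceSet:
    """Aligned sequences sharing a consensus with per-target mutations and one
    shared gappy column block, mimicking a binding-site alignment."""
    letters = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(letters, size=length)
    ids, seqs = [], []
    for t in range(n_targets):
        seq = consensus.copy()
        n_mut = max(2, length // 3)
        pos = rng.choice(length, size=n_mut, replace=False)
        seq[pos] = rng.choice(letters, size=n_mut)
        if t % 3 == 2:  # every third target carries a deletion
            seq[length - 2] = GAP
        ids.append(f"target{t + 1}")
        seqs.append("".join(seq))
    return AlignedSequenceSet(ids=tuple(ids), sequences=tuple(seqs))


def _target_effect(sequence: str) -> float:
    vals = [Z5.values[aa][0] for aa in sequence if aa != GAP]
    return float(np.mean(vals)) if vals else 0.0


def make_pcm_fixture(spec: SyntheticSpec) -> tuple[pd.DataFrame, AlignedSequenceSet, dict]:
    """Compound–target–activity table plus aligned target sequences.

    Exactly ``ceil(completeness · n_molecules · n_targets)`` distinct cells
    are retained (each compound and each target covered at least once when
    the budget allows), and the first few cells are duplicated with a second
    noisy measurement so duplicate aggregation is exercised. Activity is
    compound term + target term + interaction + noise.
    """
    if spec.pcm is None:
        raise ConfigurationError("spec.pcm must be provided for a PCM fixture")
    n_targets = int(spec.pcm["n_targets"])
    completeness = float(spec.pcm.get("completeness", 1.0))
    rng = np.random.default_rng(spec.seed)
    smiles = enumerate_molecules(spec.n_molecules)
    compound_ids = [f"syn{i + 1}" for i in range(len(smiles))]
    alignment = _synthetic_alignment(n_targets, length=15, rng=rng)
    target_effects = {tid: _target_effect(seq) for tid, seq in zip(alignment.ids, alignment.sequences)}
    compound_effects = {
        cid: _true_property(smi, spec.coefficients) for cid, smi in zip(compound_ids, smiles)
    }

    # round before ceil so 0.139·1000 = 139.000…003 does not become 140 cells
    n_cells = int(np.ceil(round(completeness * spec.n_molecules * n_targets, 9)))
    all_cells = [(i, j) for i in range(spec.n_molecules) for j in range(n_targets)]
    chosen: list[tuple[int, int]] = []
    taken = set()
    if n_cells >= spec.n_molecules:
        for i in range(spec.n_molecules):  # cover every compound
            cell = (i, int(rng.integers(n_targets)))
            chosen.append(cell)
            taken.add(cell)
    uncovered = set(range(n_targets)) - {j for _, j in chosen}
    for j in sorted(uncovered):  # cover every remaining target
        if len(chosen) >= n_cells:
            break
        free = [i for i in range(spec.n_molecules) if (i, j) not in taken]
        cell = (int(rng.choice(free)), j)
        chosen.append(cell)
        taken.add(cell)
    remaining = [c for c in all_cells if c not in taken]
    extra = n_cells - len(chosen)
    if extra > 0:
        idx = rng.choice(len(remaining), size=extra, replace=False)
        chosen.extend(remaining[int(i)] for i in idx)
    chosen = chosen[:n_cells]

    def activity(i: int, j: int) -> float:
        cid, tid = compound_ids[i], alignment.ids[j]
        base = (
            compound_effects[cid]
            + 0.8 * target_effects[tid]
            + 0.05 * compound_effects[cid] * target_effects[tid]
        )
        return base + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)

    rows = [
        {
            "compound": compound_ids[i],
            "smiles": smiles[i],
            "target": alignment.ids[j],
            "value": activity(i, j),
        }
        for i, j in chosen
    ]
    for i, j in chosen[: min(5, len(chosen))]:  # duplicated measurements
        rows.append(
            {
                "compound": compound_ids[i],
                "smiles": smiles[i],
                "target": alignment.ids[j],
                "value": activity(i, j),
            }
        )
    table = pd.DataFrame(rows)
    truth = {
        "coefficients": dict(spec.coefficients),
        "target_effects": target_effects,
        "n_distinct_cells": n_cells,
    }
    return table, alignment, truth


def write_fasta(alignment: AlignedSequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.ids, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")
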