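"""Protein-side descriptors for proteochemometrics.

Aligned binding-site (or full) sequences are turned into per-position
physicochemical descriptors by substituting each residue with its scale
vector; alignment gaps ('-') contribute zeros, so all rows share one length
and a model can compare positions across targets. Whole-sequence composition
descriptors (amino-acid and dipeptide composition) summarise an ungapped
sequence irrespective of length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .descriptors import DescriptorMatrix
from .errors import ConfigurationError, DataValidationError, DomainError
from .scales import AMINO_ACIDS, ScaleTable

GAP = "-"


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length sequences over the 20 standard amino acids plus '-'."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise DataValidationError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise DataValidationError("sequence ids are not unique")
        if self.sequences:
            L = len(self.sequences[0])
            for sid, seq in zip(self.ids, self.sequences):
                if len(seq) != L:
                    raise DataValidationError(
                        f"sequence {sid!r} has length {len(seq)}, expected {L}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignedSequenceSet":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(ids=tuple(ids), sequences=tuple(seqs))


def _check_alphabet(sid: str, seq: str, allow_gap: bool) -> None:
    alphabet = set(AMINO_ACIDS) | ({GAP} if allow_gap else set())
    for pos, letter in enumerate(seq):
        if letter not in alphabet:
            raise DataValidationError(
                f"sequence {sid!r}: unknown residue {letter!r} at position {pos}"
            )


def aa_scale_descriptors(alignment: AlignedSequenceSet, scale: ScaleTable) -> DescriptorMatrix:
    """Per-position scale descriptors for an alignment.

    Row length is ``alignment.length * scale.dims``; position ``p`` dimension
    ``d`` lands in column ``pos{p}_{scale}{d+1}``. Gap positions contribute
    ``dims`` zeros. Non-standard residue letters (B, Z, X, U...) are rejected:
    gaps are the only sanctioned zero-encoding.
    """
    for sid, seq in zip(alignment.ids, alignment.sequences):
        _check_alphabet(sid, seq, allow_gap=True)
    L, d = alignment.length, scale.dims
    X = np.zeros((len(alignment.sequences), L * d))
    for i, seq in enumerate(alignment.sequences):
        for p, letter in enumerate(seq):
            if letter != GAP:
                X[i, p * d : (p + 1) * d] = scale.values[letter]
    cols = [f"pos{p}_{scale.name}{k + 1}" for p in range(L) for k in range(d)]
    data = pd.DataFrame(X, index=pd.Index(alignment.ids, name="id"), columns=cols)
    return DescriptorMatrix(
        data=data, engine=f"aa_scale_{scale.name}", parameters={"scale": scale.name, "dims": d}
    )


_DIPEPTIDES = ["".join(p) for p in product(AMINO_ACIDS, repeat=2)]


def seq_composition(sequence: str, kind: str = "AAC") -> pd.Series:
    """Whole-sequence composition: AAC (20 residue frequencies) or DC (400
    overlapping-dipeptide frequencies). Both are relative frequencies summing to 1."""
    sequence = sequence.upper()
    _check_alphabet("<sequence>", sequence, allow_gap=False)
    if kind == "AAC":
        if len(sequence) < 1:
            raise DomainError("AAC needs a sequence of length >= 1")
        counts = pd.Series(0.0, index=list(AMINO_ACIDS))
        for letter in sequence:
            counts[letter] += 1.0
        return counts / len(sequence)
    if kind == "DC":
        if len(sequence) < 2:
            raise DomainError("DC needs a sequence of length >= 2")
        counts = pd.Series(0.0, index=_DIPEPTIDES)
        for a, b in zip(sequence, sequence[1:]):
            counts[a + b] += 1.0
        return counts / (len(sequence) - 1)
    raise ConfigurationError(f"unknown composition kind {kind!r} (use 'AAC' or 'DC')")


def composition_descriptors(
    ids: Sequence[str], sequences: Sequence[str], kind: str = "AAC"
) -> DescriptorMatrix:
    """Composition descriptor matrix for several ungapped sequences."""
    rows = [seq_composition(seq, kind) for seq in sequences]
    data = pd.DataFrame(rows, index=pd.Index(list(ids), name="id"))
    data.columns = [f"{kind.lower()}_{c}" for c in data.columns]
    return DescriptorMatrix(data=data, engine=f"composition_{kind.lower()}", parameters={"kind": kind})
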