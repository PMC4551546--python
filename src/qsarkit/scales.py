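"""Amino-acid scale tables.

A scale table assigns each of the 20 standard amino acids a short vector of
physicochemical scores. Bundled here are the classic z-scales: the
three-dimensional set derived by Hellberg et al. from a PCA of 29
physicochemical properties ("z3"), and the five-dimensional extension by
Sandberg et al. covering 87 properties ("z5"). z1 tracks
hydrophilicity, z2 steric bulk/polarisability, z3 polarity/charge; z4 and z5
capture electronegativity/heat-of-formation-type and electrophilicity-type
variation.

Other published scale sets (T-scales, VHSE, BLOSUM-derived, FASGAI, MSWHIM,
ProtFP...) can be loaded from a user CSV with :func:`load_scale_csv` rather
than being bundled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ScaleTable:
    """Per-residue descriptor vectors: each standard amino acid maps to ``dims`` reals."""

    name: str
    dims: int
    values: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.values]
        if missing:
            raise ConfigurationError(f"scale {self.name!r} missing residues {missing}")
        for aa, vec in self.values.items():
            if len(vec) != self.dims:
                raise ConfigurationError(
                    f"scale {self.name!r}: residue {aa} has {len(vec)} values, expected {self.dims}"
                )


_Z3 = {
    "A": (0.07, -1.73, 0.09),
    "V": (-2.69, -2.53, -1.29),
    "L": (-4.19, -1.03, -0.98),
    "I": (-4.44, -1.68, -1.03),
    "P": (-1.22, 0.88, 2.23),
    "F": (-4.92, 1.30, 0.45),
    "W": (-4.75, 3.65, 0.85),
    "M": (-2.49, -0.27, -0.41),
    "K": (2.84, 1.41, -3.14),
    "R": (2.88, 2.52, -3.44),
    "H": (2.41, 1.74, 1.11),
    "G": (2.23, -5.36, 0.30),
    "S": (1.96, -1.63, 0.57),
    "T": (0.92, -2.09, -1.40),
    "C": (0.71, -0.97, 4.13),
    "Y": (-1.39, 2.32, 0.01),
    "N": (3.22, 1.45, 0.84),
    "Q": (2.18, 0.53, -1.14),
    "D": (3.64, 1.13, 2.36),
    "E": (3.08, 0.39, -0.07),
}

_Z5 = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
}

Z3 = ScaleTable(name="z3", dims=3, values=_Z3)
Z5 = ScaleTable(name="z5", dims=5, values=_Z5)

SCALES: dict[str, ScaleTable] = {"z3": Z3, "z5": Z5}


def get_scale(name: str) -> ScaleTable:
    try:
        return SCALES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scale {name!r}; bundled: {sorted(SCALES)}; "
            "load others with load_scale_csv()"
        ) from None


def load_scale_csv(path: str | Path, name: str | None = None) -> ScaleTable:
    """Load a user-supplied scale table.

    Expected CSV layout: a ``letter`` column plus one column per dimension;
    all non-letter columns are taken as dimensions in file order.
    """
    path = Path(path)
    values: dict[str, tuple[float, ...]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        if "letter" not in fields:
            raise ConfigurationError("scale CSV needs a 'letter' column")
        dim_cols = [c for c in fields if c != "letter"]
        for row in reader:
            values[row["letter"].strip()] = tuple(float(row[c]) for c in dim_cols)
    return ScaleTable(name=name or path.stem, dims=len(dim_cols), values=values)
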