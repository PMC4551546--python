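"""Compound reading and standardisation.

Chemical structure strings are ambiguous: the same physical compound can be
written with different aromaticity perception, counter-ions, or tautomeric
forms. Before descriptor calculation every molecule is therefore brought to a
single canonical representation, and structures a modeller does not want
(inorganics, heavily halogenated compounds, out-of-range masses) are filtered
out. Tautomers are collapsed by converting to standard InChI — whose mobile-
hydrogen layer abstracts away N/O/S proton positions — and converting back to
a canonical SMILES.

Filters run in a fixed order (parse → inorganic → halogen → mass →
tautomer-canonicalise) so that the status assigned to a rejected molecule is
reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import ConfigurationError, ParseError

RDLogger.DisableLog("rdApp.*")

HALOGENS = ("F", "Cl", "Br", "I")

#: statuses a record can end standardisation with
STATUSES = ("kept", "removed_parse", "removed_halogen", "removed_inorganic", "removed_mass")


@dataclass
class MoleculeRecord:
    """One compound: raw structure, optional property value, final status."""

    id: str
    smiles_raw: str
    smiles_std: str | None = None
    property: float | None = None
    status: str = "kept"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ConfigurationError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class StandardizationConfig:
    """Structural filters applied during standardisation.

    ``max_halogens`` maps an element symbol (F, Cl, Br, I) to the largest
    allowed count of that element; elements absent from the map are
    unlimited. Masses are average molecular weights in Da. With
    ``keep_largest_fragment`` (default), salts/mixtures are reduced to their
    largest covalent fragment before any filter runs.
    """

    max_halogens: Mapping[str, int] = field(default_factory=dict)
    min_mass: float | None = None
    max_mass: float | None = None
    remove_inorganic: bool = False
    canonicalize_tautomers: bool = True
    keep_largest_fragment: bool = True

    def __post_init__(self) -> None:
        for el in self.max_halogens:
            if el not in HALOGENS:
                raise ConfigurationError(f"max_halogens key {el!r} is not a halogen")
        if (
            self.min_mass is not None
            and self.max_mass is not None
            and self.min_mass > self.max_mass
        ):
            raise ConfigurationError("min_mass exceeds max_mass")


def read_molecules(
    path: str | Path,
    format: str | None = None,
    property_column: str | None = None,
    smiles_column: str = "smiles",
    id_column: str = "id",
) -> list[MoleculeRecord]:
    """Read molecules from a SMILES line file, an SDF, or a CSV.

    ``format`` is one of ``"smiles"``, ``"sdf"``, ``"csv"``; when omitted it
    is inferred from the file suffix. Entries that fail to parse are retained
    with status ``removed_parse`` so the record count always matches the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smiles", ".smiles": "smiles", ".sdf": "sdf", ".csv": "csv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ConfigurationError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "smiles":
        return _read_smiles_lines(path)
    if format == "sdf":
        return _read_sdf(path, property_column)
    if format == "csv":
        return _read_csv(path, property_column, smiles_column, id_column)
    raise ConfigurationError(f"unknown molecule format {format!r}")


def _mark_parse(rec: MoleculeRecord) -> MoleculeRecord:
    if Chem.MolFromSmiles(rec.smiles_raw) is None:
        rec.status = "removed_parse"
        rec.smiles_std = None
    return rec


def _read_smiles_lines(path: Path) -> list[MoleculeRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            records.append(_mark_parse(MoleculeRecord(id=mol_id, smiles_raw=smiles)))
    return records


def _read_sdf(path: Path, property_column: str | None) -> list[MoleculeRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                MoleculeRecord(id=f"mol{i + 1}", smiles_raw="", status="removed_parse")
            )
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
        prop = None
        if property_column is not None and mol.HasProp(property_column):
            prop = float(mol.GetProp(property_column))
        records.append(
            MoleculeRecord(id=mol_id, smiles_raw=Chem.MolToSmiles(mol), property=prop)
        )
    return records


def _read_csv(
    path: Path, property_column: str | None, smiles_column: str, id_column: str
) -> list[MoleculeRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        if smiles_column not in fields:
            raise ConfigurationError(f"CSV lacks smiles column {smiles_column!r}")
        if property_column is not None and property_column not in fields:
            raise ConfigurationError(f"CSV lacks property column {property_column!r}")
        for i, row in enumerate(reader):
            prop = None
            if property_column is not None and row[property_column] not in ("", None):
                prop = float(row[property_column])
            mol_id = row.get(id_column) or f"mol{i + 1}"
            records.append(
                _mark_parse(
                    MoleculeRecord(id=mol_id, smiles_raw=row[smiles_column], property=prop)
                )
            )
    return records


def canonical_tautomer_smiles(smiles: str) -> str:
    """Collapse tautomers to one canonical SMILES via a standard-InChI round trip.

    Standard InChI stores N/O/S-bound mobile hydrogens in a delocalised
    layer, so any two such tautomers share one InChI; converting back gives a
    single canonical SMILES for the whole tautomer family. The map is
    idempotent. Note that C–H tautomerism (keto–enol) is outside standard
    InChI's mobile-H model and is deliberately not collapsed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        raise ParseError(f"InChI conversion failed for {smiles!r}")
    back = Chem.MolFromInchi(inchi)
    if back is None:
        raise ParseError(f"InChI round trip failed for {smiles!r}")
    return Chem.MolToSmiles(back)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda f: f.GetNumAtoms())


def standardise_molecules(
    records: Iterable[MoleculeRecord], config: StandardizationConfig | None = None
) -> list[MoleculeRecord]:
    """Assign every record a final status and, for kept records, a canonical SMILES.

    Deterministic: identical input and config give identical output. Records
    already marked ``removed_parse`` pass through unchanged.
    """
    config = config or StandardizationConfig()
    out: list[MoleculeRecord] = []
    for rec in records:
        out.append(_standardise_one(rec, config))
    return out


def _standardise_one(rec: MoleculeRecord, config: StandardizationConfig) -> MoleculeRecord:
    rec = replace(rec)
    if rec.status == "removed_parse":
        rec.smiles_std = None
        return rec
    mol = Chem.MolFromSmiles(rec.smiles_raw)
    if mol is None:
        rec.status = "removed_parse"
        rec.smiles_std = None
        return rec
    if config.keep_largest_fragment and len(Chem.GetMolFrags(mol)) > 1:
        mol = _largest_fragment(mol)
        Chem.SanitizeMol(mol)
    if config.remove_inorganic and not any(
        a.GetSymbol() == "C" for a in mol.GetAtoms()
    ):
        rec.status = "removed_inorganic"
        rec.smiles_std = None
        return rec
    for el, limit in config.max_halogens.items():
        count = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == el)
        if count > limit:
            rec.status = "removed_halogen"
            rec.smiles_std = None
            return rec
    mass = Descriptors.MolWt(mol)
    if (config.min_mass is not None and mass < config.min_mass) or (
        config.max_mass is not None and mass > config.max_mass
    ):
        rec.status = "removed_mass"
        rec.smiles_std = None
        return rec
    smiles = Chem.MolToSmiles(mol)
    if config.canonicalize_tautomers:
        try:
            smiles = canonical_tautomer_smiles(smiles)
        except ParseError:
            rec.status = "removed_parse"
            rec.smiles_std = None
            return rec
    rec.status = "kept"
    rec.smiles_std = smiles
    return rec


def kept(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """The records that survived standardisation."""
    return [r for r in records if r.status == "kept"]


def write_standardised_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles_std", "status", "property"])
        for r in records:
            writer.writerow(
                [r.id, r.smiles_std or "", r.status, "" if r.property is None else repr(r.property)]
            )
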