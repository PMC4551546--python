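"""Bundled reference tables.

COX_INHIBITION_SUMMARY is the published per-protein datapoint census of the
mammalian cyclooxygenase (COX-1/COX-2) inhibition dataset assembled from
ChEMBL 16: 3,228 distinct compounds measured by IC50 against 11 orthologous
and paralogous COX enzymes. It is the canonical worked example for
compound×target matrix-completeness summaries; the underlying bioactivity
records themselves are not shipped.
"""

from __future__ import annotations

import pandas as pd

from .cv import matrix_completeness

#: (UniProt id, isoenzyme, organism, number of datapoints)
COX_INHIBITION_SUMMARY: list[tuple[str, int, str, int]] = [
    ("P23219", 1, "Homo sapiens", 1346),
    ("O62664", 1, "Bos taurus", 48),
    ("P22437", 1, "Mus musculus", 50),
    ("O97554", 1, "Oryctolagus cuniculus", 11),
    ("P05979", 1, "Ovis aries", 442),
    ("Q63921", 1, "Rattus norvegicus", 23),
    ("P35354", 2, "Homo sapiens", 2311),
    ("O62698", 2, "Bos taurus", 21),
    ("Q05769", 2, "Mus musculus", 305),
    ("P79208", 2, "Ovis aries", 341),
    ("P35355", 2, "Rattus norvegicus", 39),
]

#: distinct compounds in the COX dataset
COX_N_COMPOUNDS = 3228


def cox_summary_frame() -> pd.DataFrame:
    return pd.DataFrame(
        COX_INHIBITION_SUMMARY,
        columns=["uniprot_id", "isoenzyme", "organism", "n_datapoints"],
    )


def cox_dataset_stats() -> dict:
    """Totals and matrix completeness of the COX inhibition dataset."""
    df = cox_summary_frame()
    total = int(df["n_datapoints"].sum())
    return {
        "n_compounds": COX_N_COMPOUNDS,
        "n_targets": len(df),
        "n_datapoints": total,
        "completeness_pct": matrix_completeness(COX_N_COMPOUNDS, len(df), total),
    }
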