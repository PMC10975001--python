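"""Bundled reference datasets.

Small published summary tables re-encoded as TSV, used as desk-scale input
fixtures: the five-compound transferred-metabolite intensity table, the
50-gene mobile-gene FPKM table, the 44-gene chimera-induced gene table, and
the 56-compound co-regulation (type-pair) table.  Each compartment appears
as a single column because the sources print one aggregate value per
compartment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dam_screen import CoRegulationRecord
from .io_formats import COMPARTMENTS, FeatureTable

__all__ = [
    "load_transferred_metabolite_intensities",
    "load_mobile_gene_fpkm",
    "load_chimera_induced_gene_fpkm",
    "load_coregulation_records",
]


def _data_path(name: str):
    return resources.files("hausflow.data").joinpath(name)


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


_SINGLE_SAMPLE_MAP = {c: c for c in COMPARTMENTS}


def _to_feature_table(raw: pd.DataFrame, id_col: str, kind: str) -> FeatureTable:
    frame = raw.set_index(id_col)[list(COMPARTMENTS)]
    frame = frame.apply(lambda col: pd.to_numeric(col.replace("-", None)))
    meta_cols = [c for c in raw.columns if c not in (id_col, *COMPARTMENTS)]
    meta = {
        row[id_col]: {c: row[c] for c in meta_cols} for _, row in raw.iterrows()
    }
    return FeatureTable(
        frame=frame,
        sample_to_compartment=dict(_SINGLE_SAMPLE_MAP),
        feature_kind=kind,
        feature_meta=meta,
    )


def load_transferred_metabolite_intensities() -> FeatureTable:
    """Five-compound intensity table; '-' cells are undetected (missing)."""
    return _to_feature_table(
        _read("transferred_metabolite_intensities.tsv"), "compound", "metabolite"
    )


def load_mobile_gene_fpkm() -> FeatureTable:
    """The 50 mobile-gene candidates with one FPKM value per compartment."""
    return _to_feature_table(_read("mobile_gene_fpkm.tsv"), "unigene_id", "gene")


def load_chimera_induced_gene_fpkm() -> FeatureTable:
    """The 44 chimera-upregulated genes with one FPKM value per compartment."""
    return _to_feature_table(_read("chimera_induced_gene_fpkm.tsv"), "unigene_id", "gene")


def load_coregulation_records() -> list[CoRegulationRecord]:
    """The 56 metabolites differential in both comparisons, with type pairs."""
    raw = _read("coregulated_metabolite_types.tsv")
    return [
        CoRegulationRecord(
            feature_id=row["compound"],
            type_pair=(row["type_TH_vs_THC"], row["type_P_vs_PC"]),
        )
        for _, row in raw.iterrows()
    ]
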