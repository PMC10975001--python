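"""Readers and writers for every external format the pipeline touches.

The central in-memory object is :class:`FeatureTable`, a features x samples
abundance matrix (metabolite intensities or gene FPKM) with a sample ->
compartment map over the four-compartment design (intact parasite ``TH``,
parasite chimera ``THC``, host chimera ``PC``, intact host ``P``).

Missing values (undetected metabolites) are held as ``NaN`` and are distinct
from measured zeros unless the dialect says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

COMPARTMENTS: tuple[str, ...] = ("TH", "THC", "PC", "P")

__all__ = [
    "COMPARTMENTS",
    "TableDialect",
    "FeatureTable",
    "OriginHit",
    "read_feature_table",
    "write_feature_table",
    "read_sample_map",
    "read_blast_tab",
    "read_fasta",
    "write_fasta",
    "write_edge_table",
]


@dataclass(frozen=True)
class TableDialect:
    """How a delimited abundance table encodes its cells.

    ``missing_markers`` are accepted on input; ``missing_repr`` is the single
    marker emitted on output.  Thousands separators ("35,397") are accepted on
    input and never emitted.  With ``zero_is_missing`` a numeric 0 collapses
    into missing on input.
    """

    delimiter: str = "\t"
    missing_markers: tuple[str, ...] = ("", "NA", "-")
    missing_repr: str = "-"
    zero_is_missing: bool = False


@dataclass
class FeatureTable:
    """Features x samples abundance matrix with compartment labels.

    Parameters
    ----------
    frame
        Float DataFrame, rows = feature ids, columns = sample ids, ``NaN`` =
        missing.  Values must be non-negative.
    sample_to_compartment
        Map from every sample id to one of ``COMPARTMENTS``.
    feature_kind
        ``"metabolite"`` (raw intensity) or ``"gene"`` (FPKM).
    feature_meta
        Optional per-feature annotation, e.g. ``{"category": ..., "annotation": ...}``.
    """

    frame: pd.DataFrame
    sample_to_compartment: dict[str, str]
    feature_kind: str = "metabolite"
    feature_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_kind not in ("metabolite", "gene"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.frame.columns.has_duplicates:
            dup = self.frame.columns[self.frame.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        for s in self.frame.columns:
            comp = self.sample_to_compartment.get(s)
            if comp is None:
                raise ValueError(f"sample {s!r} has no compartment mapping")
            if comp not in COMPARTMENTS:
                raise ValueError(f"sample {s!r} maps to unknown compartment {comp!r}")
        self.frame = self.frame.astype(float)
        vals = self.frame.to_numpy()
        neg = vals < 0  # NaN-safe: NaN < 0 is False
        if neg.any():
            bad = self.frame.index[neg.any(axis=1)][0]
            raise ValueError(f"negative abundance for feature {bad!r}")

    # -- basic accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_features(self) -> int:
        return self.frame.shape[0]

    def samples_in(self, compartment: str) -> list[str]:
        """Sample ids belonging to one compartment, column order preserved."""
        return [s for s in self.frame.columns if self.sample_to_compartment[s] == compartment]

    def present_compartments(self) -> list[str]:
        return [c for c in COMPARTMENTS if self.samples_in(c)]

    def require_compartments(self, needed: Iterable[str] = COMPARTMENTS) -> None:
        for c in needed:
            if not self.samples_in(c):
                raise ValueError(f"compartment {c!r} has no samples")

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        return replace(
            self,
            frame=self.frame.loc[list(ids)],
            feature_meta={k: v for k, v in self.feature_meta.items() if k in set(ids)},
        )

    def subset_samples(self, ids: Sequence[str]) -> "FeatureTable":
        return replace(
            self,
            frame=self.frame[list(ids)],
            sample_to_compartment={s: self.sample_to_compartment[s] for s in ids},
        )

    def compartment_means(
        self, aggregation: str = "mean", missing_as_zero: bool = True
    ) -> pd.DataFrame:
        """Per-compartment replicate aggregate, features x compartments.

        With ``missing_as_zero`` undetected cells count as 0 (the convention
        used for fold changes and FPKM thresholding); otherwise they are
        excluded from the aggregate.
        """
        if aggregation not in ("mean", "median"):
            raise ValueError(f"unknown aggregation {aggregation!r}")
        frame = self.frame.fillna(0.0) if missing_as_zero else self.frame
        out = {}
        for comp in self.present_compartments():
            block = frame[self.samples_in(comp)]
            out[comp] = block.mean(axis=1) if aggregation == "mean" else block.median(axis=1)
        return pd.DataFrame(out)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.frame.equals(other.frame)
            and self.sample_to_compartment == other.sample_to_compartment
            and self.feature_kind == other.feature_kind
        )


@dataclass(frozen=True)
class OriginHit:
    """One alignment hit of a unigene against a reference genome."""

    query_id: str
    subject_genome: str  # "parasite_ref" | "host_ref"
    bitscore: float
    evalue: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not np.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, dialect: TableDialect, where: str) -> float:
    token = raw.strip()
    if token in dialect.missing_markers:
        return np.nan
    token = token.replace(",", "")  # thousands separators, accepted never emitted
    try:
        value = float(token)
    except ValueError as exc:
        raise ValueError(f"cannot parse abundance {raw!r} at {where}") from exc
    if value < 0:
        raise ValueError(f"negative abundance {raw!r} at {where}")
    if dialect.zero_is_missing and value == 0:
        return np.nan
    return value


def _infer_compartment(sample_id: str) -> str:
    for comp in sorted(COMPARTMENTS, key=len, reverse=True):
        if sample_id == comp or (
            sample_id.startswith(comp) and not sample_id[len(comp)].isalpha()
        ):
            return comp
    raise ValueError(f"sample {sample_id!r} has no compartment mapping")


def read_sample_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>compartment`` file (no header)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        sample, comp = (f.strip() for f in fields)
        if comp not in COMPARTMENTS:
            raise ValueError(f"{path}:{lineno}: unknown compartment {comp!r}")
        mapping[sample] = comp
    return mapping


def read_feature_table(
    path: str | Path,
    sample_map: Mapping[str, str] | str | Path | None = None,
    dialect: TableDialect | None = None,
    feature_kind: str = "metabolite",
) -> FeatureTable:
    """Read a delimited abundance table (first column feature id, header row
    of sample ids).

    ``sample_map`` may be a dict, a path to a two-column map file, or ``None``
    to derive compartments from sample ids of the form ``TH_1`` / ``PC2`` /
    ``P`` (header-encoded labels).
    """
    dialect = dialect or TableDialect()
    raw = pd.read_csv(
        Path(path), sep=dialect.delimiter, dtype=str, keep_default_na=False, header=0
    )
    feature_col = raw.columns[0]
    sample_ids = [str(c) for c in raw.columns[1:]]

    feature_ids: list[str] = []
    seen: set[str] = set()
    for fid in raw[feature_col].astype(str):
        if fid in seen:
            raise ValueError(f"duplicate feature id {fid!r} in {path}")
        seen.add(fid)
        feature_ids.append(fid)

    values = np.empty((len(feature_ids), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        col = raw[raw.columns[j + 1]]
        for i, cell in enumerate(col):
            values[i, j] = _parse_cell(str(cell), dialect, f"{path} row {feature_ids[i]!r}")

    if sample_map is None:
        mapping = {s: _infer_compartment(s) for s in sample_ids}
    elif isinstance(sample_map, (str, Path)):
        mapping = read_sample_map(sample_map)
    else:
        mapping = dict(sample_map)
    for s in sample_ids:
        if s not in mapping:
            raise ValueError(f"sample {s!r} has no compartment mapping")

    frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return FeatureTable(
        frame=frame,
        sample_to_compartment={s: mapping[s] for s in sample_ids},
        feature_kind=feature_kind,
    )


def _format_cell(value: float, dialect: TableDialect) -> str:
    if np.isnan(value):
        return dialect.missing_repr
    return repr(float(value))


def write_feature_table(
    table: FeatureTable, path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write a table so that ``read_feature_table`` round-trips it exactly."""
    dialect = dialect or TableDialect()
    lines = [dialect.delimiter.join(["feature_id", *table.sample_ids])]
    for fid in table.feature_ids:
        row = table.frame.loc[fid]
        cells = [_format_cell(row[s], dialect) for s in table.sample_ids]
        lines.append(dialect.delimiter.join([fid, *cells]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# alignment hits
# ---------------------------------------------------------------------------


def read_blast_tab(
    path: str | Path,
    subject_map: Mapping[str, str] | str | Path,
    evalue_max: float = 1e-10,
) -> list[OriginHit]:
    """Parse 12-column tabular alignment output (``-outfmt 6``).

    Hits with ``evalue > evalue_max`` are dropped (the boundary value is
    retained).  ``subject_map`` maps subject sequence ids to ``parasite_ref``
    or ``host_ref``.
    """
    if isinstance(subject_map, (str, Path)):
        mapping = {}
        for lineno, line in enumerate(Path(subject_map).read_text().splitlines(), 1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{subject_map}:{lineno}: expected 2 fields")
            mapping[fields[0].strip()] = fields[1].strip()
    else:
        mapping = dict(subject_map)

    hits: list[OriginHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ValueError(f"{path}:{lineno}: expected 12 fields, got {len(fields)}")
        query, subject = fields[0], fields[1]
        evalue = float(fields[10])
        bitscore = float(fields[11])
        if subject not in mapping:
            raise ValueError(f"{path}:{lineno}: subject {subject!r} not in subject map")
        genome = mapping[subject]
        if genome not in ("parasite_ref", "host_ref"):
            raise ValueError(f"{path}:{lineno}: unknown genome label {genome!r}")
        if evalue > evalue_max:
            continue
        hits.append(
            OriginHit(
                query_id=query,
                subject_genome=genome,
                bitscore=bitscore,
                evalue=evalue,
                subject_id=subject,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: upper-cased sequence}``.

    The id is the first whitespace-delimited token of the header.  Duplicate
    ids and empty sequences are hard errors.
    """
    records: dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise ValueError(f"FASTA record with empty id in {path}")
            if name in records:
                raise ValueError(f"duplicate FASTA id {name!r} in {path}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for FASTA id {name!r} in {path}")
            records[name] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# network edge export
# ---------------------------------------------------------------------------


def write_edge_table(edges: Iterable, path: str | Path, format: str = "edge_tsv") -> None:
    """Write network edges as a TSV edge list or a SIF file.

    Edges are any objects with ``gene_id``, ``metabolite_id``, ``pcc``,
    ``p_value`` and ``sign`` attributes.  Output ordering is deterministic:
    (source, target) lexicographic.
    """
    ordered = sorted(edges, key=lambda e: (e.gene_id, e.metabolite_id))
    if format == "edge_tsv":
        lines = ["source\ttarget\tpcc\tp_value\tsign"]
        for e in ordered:
            lines.append(f"{e.gene_id}\t{e.metabolite_id}\t{e.pcc!r}\t{e.p_value!r}\t{e.sign}")
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "sif":
        lines = [f"{e.gene_id}\t{e.sign}\t{e.metabolite_id}" for e in ordered]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown edge table format {format!r}")
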