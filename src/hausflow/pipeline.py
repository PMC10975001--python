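"""End-to-end orchestration: screen -> origin -> mobility -> network.

A :class:`PipelineConfig` carries every input path, numeric cutoff and mode;
:func:`run_pipeline` executes the stages, writes deterministic outputs under
``out_dir`` and returns a :class:`RunReport` of per-stage counts.  Identical
config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import dam_screen, haustoria_network, mobility, origin_assign
from .io_formats import (
    COMPARTMENTS,
    TableDialect,
    read_blast_tab,
    read_fasta,
    read_feature_table,
    write_edge_table,
)

logger = logging.getLogger("hausflow")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and modes for one pipeline run.

    Threshold defaults are the study cutoffs: VIP >= 1, |log2FC| >= 1,
    FPKM presence cut 3, intact-root cut 0.3, |PCC| > 0.80, p < 0.05,
    alignment e-value <= 1e-10.
    """

    metabolites: Optional[str] = None
    genes: Optional[str] = None
    sample_map: Optional[str] = None
    blast_hits: Optional[str] = None
    subject_map: Optional[str] = None
    unigenes: Optional[str] = None
    genome_parasite: Optional[str] = None
    genome_host: Optional[str] = None
    out_dir: str = "hausflow_out"

    vip_min: float = 1.0
    fc_min: float = 1.0
    fpkm_min: float = 3.0
    fpkm_intact_max: float = 0.3
    pcc_min: float = 0.80
    p_max: float = 0.05
    evalue_max: float = 1e-10
    detection_limit: float = 0.0
    kmer_k: int = 21
    kmer_min_score: float = 0.5

    intact_mode: str = "any"
    zero_is_missing: bool = False
    aggregation: str = "mean"
    n_orthogonal: int = 1
    min_detect_reps: Optional[int] = None
    network_samples: str = "chimera"  # or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vip_min", "fc_min", "fpkm_min", "fpkm_intact_max", "pcc_min", "p_max", "evalue_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land does not change them
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage counts plus the paths of every file written."""

    config_hash: str
    n_metabolites: int = 0
    n_genes: int = 0
    n_dams: dict[str, int] = field(default_factory=dict)
    n_common_dams: int = 0
    n_transferred: dict[str, int] = field(default_factory=dict)
    n_mobile: dict[str, int] = field(default_factory=dict)
    n_haustoria_genes: int = 0
    n_edges: int = 0
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(c) for c in row))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every configured stage; on failure, remove partial outputs and
    re-raise naming the stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash())
    written: list[Path] = []
    dialect = TableDialect(zero_is_missing=config.zero_is_missing)

    def emit(name: str, path: Path) -> None:
        written.append(path)
        report.outputs[name] = path.name  # relative: report stays path-independent

    stage = "load_inputs"
    try:
        metab = gene = None
        if config.metabolites:
            metab = read_feature_table(
                config.metabolites, config.sample_map, dialect, feature_kind="metabolite"
            )
            report.n_metabolites = metab.n_features
        if config.genes:
            gene = read_feature_table(
                config.genes, config.sample_map, dialect, feature_kind="gene"
            )
            report.n_genes = gene.n_features
        logger.info("loaded inputs: %d metabolites, %d genes", report.n_metabolites, report.n_genes)

        # -- differential metabolites ---------------------------------
        stage = "dam_screen"
        common = []
        enough_reps = metab is not None and all(
            len(metab.samples_in(c)) >= 2 for c in metab.present_compartments()
        )
        if metab is not None and not enough_reps:
            logger.warning("dam_screen skipped: needs >= 2 replicates per compartment")
        if metab is not None and enough_reps:
            dams = {}
            for ref, test in (("TH", "THC"), ("P", "PC")):
                recs = dam_screen.screen_dams(
                    metab,
                    (ref, test),
                    vip_min=config.vip_min,
                    fc_min=config.fc_min,
                    n_orthogonal=config.n_orthogonal,
                    aggregation=config.aggregation,
                )
                key = f"{ref}_vs_{test}"
                dams[key] = recs
                sig = [r for r in recs if r.regulation != "not_significant"]
                report.n_dams[key] = len(sig)
                path = out / f"dams_{key}.tsv"
                _write_tsv(
                    path,
                    ["feature_id", "log2fc", "vip", "regulation"],
                    [[r.feature_id, repr(r.log2fc), repr(r.vip), r.regulation] for r in recs],
                )
                emit(f"dams_{key}", path)
            common = dam_screen.coregulation_classes(dams["TH_vs_THC"], dams["P_vs_PC"])
            report.n_common_dams = len(common)
            path = out / "coregulation.tsv"
            _write_tsv(
                path,
                ["feature_id", "type_TH_vs_THC", "type_P_vs_PC"],
                [[r.feature_id, r.type_pair[0], r.type_pair[1]] for r in common],
            )
            emit("coregulation", path)
            logger.info("dam_screen: %s, %d common", report.n_dams, report.n_common_dams)

        # -- origin assignment (optional) -----------------------------
        stage = "origin_assign"
        origin_calls = None
        if config.blast_hits and config.subject_map:
            hits = read_blast_tab(config.blast_hits, config.subject_map, config.evalue_max)
            origin_calls = origin_assign.assign_from_hits(hits)
        elif config.unigenes and config.genome_parasite and config.genome_host:
            unigenes = read_fasta(config.unigenes)
            genome_p = "".join(read_fasta(config.genome_parasite).values())
            genome_h = "".join(read_fasta(config.genome_host).values())
            origin_calls = origin_assign.kmer_assign(
                unigenes, genome_p, genome_h, k=config.kmer_k, min_score=config.kmer_min_score
            )
        if origin_calls is not None:
            path = out / "origin_calls.tsv"
            _write_tsv(
                path,
                ["query_id", "assigned_genome", "score", "margin"],
                [[c.query_id, c.assigned_genome, repr(c.score), repr(c.margin)] for c in origin_calls],
            )
            emit("origin_calls", path)
            logger.info("origin_assign: %d calls", len(origin_calls))

        # -- mobility -------------------------------------------------
        stage = "mobility"
        report.n_transferred = {"host_to_parasite": 0, "parasite_to_host": 0}
        if metab is not None and metab.n_features > 0:
            transfers = mobility.classify_transfer(
                metab,
                detection_limit=config.detection_limit,
                min_detect_reps=config.min_detect_reps,
            )
            for c in transfers:
                if c.direction != mobility.NONE:
                    report.n_transferred[c.direction] += 1
            path = out / "transfer_calls.tsv"
            _write_tsv(
                path,
                ["feature_id", "direction", *COMPARTMENTS],
                [
                    [c.feature_id, c.direction]
                    + ["-" if v is None else repr(v) for v in c.intensities]
                    for c in transfers
                    if c.direction != mobility.NONE
                ],
            )
            emit("transfer_calls", path)
        report.n_mobile = {"th_to_p": 0, "p_to_th": 0}
        if gene is not None and gene.n_features > 0:
            mobiles = mobility.detect_mobile_genes(
                gene,
                fpkm_min=config.fpkm_min,
                origin_calls=origin_calls,
                aggregation=config.aggregation,
            )
            for c in mobiles:
                if c.direction != mobility.NONE:
                    report.n_mobile[c.direction] += 1
            path = out / "mobility_calls.tsv"
            _write_tsv(
                path,
                ["feature_id", "direction", *COMPARTMENTS],
                [
                    [c.feature_id, c.direction, *map(repr, c.fpkm_means)]
                    for c in mobiles
                    if c.direction != mobility.NONE
                ],
            )
            emit("mobility_calls", path)
        logger.info("mobility: %s transferred, %s mobile", report.n_transferred, report.n_mobile)

        # -- haustoria genes and network ------------------------------
        stage = "haustoria_network"
        if gene is not None and gene.n_features > 0:
            calls = haustoria_network.select_haustoria_genes(
                gene,
                fpkm_intact_max=config.fpkm_intact_max,
                intact_mode=config.intact_mode,
                fc_min=config.fc_min,
                aggregation=config.aggregation,
            )
            selected_genes = [c.feature_id for c in calls if c.qualifies]
            report.n_haustoria_genes = len(selected_genes)
            path = out / "haustoria_genes.tsv"
            _write_tsv(
                path,
                ["feature_id", *COMPARTMENTS, "up_THC", "up_PC", "qualifies"],
                [
                    [c.feature_id, *map(repr, c.fpkm_means), c.upregulated_thc, c.upregulated_pc, c.qualifies]
                    for c in calls
                    if c.qualifies
                ],
            )
            emit("haustoria_genes", path)

            edges = []
            selected_metabs = [r.feature_id for r in common]
            if selected_genes and selected_metabs and metab is not None:
                shared = [s for s in gene.sample_ids if s in set(metab.sample_ids)]
                if config.network_samples != "all":
                    shared = [s for s in shared if gene.sample_to_compartment[s] in ("THC", "PC")]
                if len(shared) >= 3:
                    edges = haustoria_network.pearson_network(
                        gene.subset_features(selected_genes),
                        metab.subset_features(selected_metabs),
                        samples=shared,
                        pcc_min=config.pcc_min,
                        p_max=config.p_max,
                    )
                else:
                    logger.warning("network skipped: fewer than 3 shared samples")
            report.n_edges = len(edges)
            epath = out / "network_edges.tsv"
            write_edge_table(edges, epath, format="edge_tsv")
            emit("network_edges", epath)
            spath = out / "network.sif"
            write_edge_table(edges, spath, format="sif")
            emit("network_sif", spath)
            npath = out / "network_nodes.tsv"
            node_rows = [[g, "gene"] for g in sorted(selected_genes)] + [
                [m, "metabolite"] for m in sorted(selected_metabs)
            ]
            _write_tsv(npath, ["node", "type"], node_rows)
            emit("network_nodes", npath)
            logger.info(
                "haustoria_network: %d genes, %d edges", report.n_haustoria_genes, report.n_edges
            )

        stage = "report"
        rpath = out / "report.json"
        report.to_json(rpath)
        emit("report", rpath)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def setup_logging(log_level: str = "INFO", log_file: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=getattr(logging, log_level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
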