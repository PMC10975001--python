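"""Synthetic four-compartment experiments with planted ground truth.

Generates a gene FPKM table and a metabolite intensity table over the
TH / THC / PC / P design (n replicates each), two synthetic reference
genomes, unigene sequences sampled verbatim from them, and a
:class:`SyntheticTruth` record of everything that was planted: mobile genes
with direction, transferred metabolites with direction, haustoria-formation
genes, differential metabolites per comparison and latent-factor-correlated
gene/metabolite pairs.

Planted features keep a >= 2x margin on both sides of every downstream
threshold, so at small replicate noise the classification stages recover the
truth exactly; background features are kept out of the decision boundary
zones for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import COMPARTMENTS, FeatureTable

__all__ = ["SimParams", "SyntheticTruth", "generate_experiment", "write_experiment"]

# thresholds the planted margins are built around (pipeline defaults)
_FPKM_MIN = 3.0
_FPKM_INTACT_MAX = 0.3


@dataclass(frozen=True)
class SimParams:
    """Knobs for one synthetic experiment."""

    n_genes: int = 2000
    n_metabolites: int = 500
    n_reps_per_compartment: int = 3
    n_mobile_th_to_p: int = 44
    n_mobile_p_to_th: int = 6
    n_transferred_host_to_parasite: int = 4
    n_transferred_parasite_to_host: int = 1
    n_haustoria_genes: int = 20
    n_common_dams: int = 56
    n_correlated_pairs: int = 10
    base_abundance_log_mean: float = 4.0  # gene FPKM scale, ln units
    metabolite_log_mean: float = 10.0  # metabolite intensity scale, ln units
    log_sd: float = 1.0
    noise_cv: float = 0.05
    detection_limit: float = 100.0
    fold_change_planted: float = 4.0
    latent_strength: float = 0.35  # log-scale latent factor for correlated pairs
    negative_pair_fraction: float = 0.0
    genome_length: int = 30000
    unigene_length: tuple[int, int] = (300, 900)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_metabolites <= 0:
            raise ValueError("n_genes and n_metabolites must be positive")
        if self.n_reps_per_compartment < 2:
            raise ValueError("need >= 2 replicates per compartment")
        if not 0 < self.noise_cv < 1:
            raise ValueError("noise_cv must lie in (0, 1)")
        if self.fold_change_planted <= 1:
            raise ValueError("fold_change_planted must be > 1")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        n_planted_genes = (
            self.n_mobile_th_to_p
            + self.n_mobile_p_to_th
            + self.n_haustoria_genes
            + self.n_correlated_pairs
        )
        if n_planted_genes > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        n_planted_metabs = (
            self.n_transferred_host_to_parasite
            + self.n_transferred_parasite_to_host
            + self.n_common_dams
            + self.n_correlated_pairs
        )
        if n_planted_metabs > self.n_metabolites:
            raise ValueError("planted metabolite counts exceed n_metabolites")
        if self.detection_limit <= 0 and (
            self.n_transferred_host_to_parasite or self.n_transferred_parasite_to_host
        ):
            raise ValueError(
                "planted transferred metabolites need detection_limit > 0 "
                "(absence is emitted as below-detection missingness)"
            )
        if not 0 <= self.negative_pair_fraction <= 1:
            raise ValueError("negative_pair_fraction must lie in [0, 1]")
        if self.genome_length < max(self.unigene_length) * 2:
            raise ValueError("genome_length too small for the unigene length range")


@dataclass
class SyntheticTruth:
    """Ground truth of everything planted in one experiment."""

    mobile_genes: dict[str, str] = field(default_factory=dict)  # id -> direction
    transferred_metabolites: dict[str, str] = field(default_factory=dict)
    haustoria_genes: set[str] = field(default_factory=set)
    dam_up: dict[str, set[str]] = field(default_factory=dict)  # comparison -> ids
    dam_down: dict[str, set[str]] = field(default_factory=dict)
    correlated_pairs: set[tuple[str, str, str]] = field(default_factory=set)
    gene_origin: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mobile_genes": self.mobile_genes,
            "transferred_metabolites": self.transferred_metabolites,
            "haustoria_genes": sorted(self.haustoria_genes),
            "dam_up": {k: sorted(v) for k, v in self.dam_up.items()},
            "dam_down": {k: sorted(v) for k, v in self.dam_down.items()},
            "correlated_pairs": sorted(list(p) for p in self.correlated_pairs),
            "gene_origin": self.gene_origin,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            mobile_genes=raw["mobile_genes"],
            transferred_metabolites=raw["transferred_metabolites"],
            haustoria_genes=set(raw["haustoria_genes"]),
            dam_up={k: set(v) for k, v in raw["dam_up"].items()},
            dam_down={k: set(v) for k, v in raw["dam_down"].items()},
            correlated_pairs={tuple(p) for p in raw["correlated_pairs"]},
            gene_origin=raw["gene_origin"],
        )


def _sample_ids(n_reps: int) -> tuple[list[str], dict[str, str]]:
    ids, mapping = [], {}
    for comp in COMPARTMENTS:
        for r in range(1, n_reps + 1):
            sid = f"{comp}_{r}"
            ids.append(sid)
            mapping[sid] = comp
    return ids, mapping


def _lognormal_means(rng, n, log_mean, log_sd, floor=None, exclude=None):
    """Draw feature means; optionally clip to >= floor and push draws out of a
    (lo, hi) exclusion zone so noisy replicates cannot straddle a threshold."""
    m = np.exp(rng.normal(log_mean, log_sd, size=n))
    if floor is not None:
        m = np.maximum(m, floor)
    if exclude is not None:
        lo, hi = exclude
        mid = np.sqrt(lo * hi)
        inside = (m > lo) & (m < hi)
        m[inside] = np.where(m[inside] >= mid, hi, lo)
    return m


def generate_experiment(
    params: SimParams,
) -> tuple[FeatureTable, FeatureTable, dict[str, str], dict[str, str], SyntheticTruth]:
    """Generate one experiment.

    Returns ``(gene_table, metabolite_table, genomes, unigenes, truth)`` where
    ``genomes`` maps ``parasite_ref``/``host_ref`` to a synthetic genome
    sequence and ``unigenes`` maps each gene id to a verbatim substring of its
    origin genome.  Identical params (including seed) give identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_reps = params.n_reps_per_compartment
    sample_ids, sample_map = _sample_ids(n_reps)
    comp_of = np.array([sample_map[s] for s in sample_ids])
    chimera_cols = np.isin(comp_of, ("THC", "PC"))
    fc = params.fold_change_planted
    sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))

    truth = SyntheticTruth(
        dam_up={"TH_vs_THC": set(), "P_vs_PC": set()},
        dam_down={"TH_vs_THC": set(), "P_vs_PC": set()},
    )

    # ----- gene compartment means -------------------------------------
    gene_ids = [f"G{i:05d}" for i in range(1, params.n_genes + 1)]
    gm = np.zeros((params.n_genes, 4))  # columns follow COMPARTMENTS order
    origin = np.empty(params.n_genes, dtype=object)

    idx = 0
    mobile_margin = 4.0 * _FPKM_MIN  # >= 2x above threshold even after averaging
    # "silent" band: comfortably below the presence cut (3) but above the
    # intact-root cut (0.3), so silenced mobile genes never look haustorial
    lo_band = (0.5, 1.4)

    def lo_vals(n):
        return rng.uniform(*lo_band, size=n)

    # mobile parasite -> host: present in TH, THC, PC; silent in P
    for _ in range(params.n_mobile_th_to_p):
        present = _lognormal_means(rng, 3, params.base_abundance_log_mean, params.log_sd, floor=mobile_margin)
        gm[idx, :3] = present
        gm[idx, 3] = lo_vals(1)[0]
        origin[idx] = "parasite_ref"
        truth.mobile_genes[gene_ids[idx]] = "th_to_p"
        idx += 1
    # mobile host -> parasite: silent in TH, present elsewhere
    for _ in range(params.n_mobile_p_to_th):
        present = _lognormal_means(rng, 3, params.base_abundance_log_mean, params.log_sd, floor=mobile_margin)
        gm[idx, 0] = lo_vals(1)[0]
        gm[idx, 1:] = present
        origin[idx] = "host_ref"
        truth.mobile_genes[gene_ids[idx]] = "p_to_th"
        idx += 1
    # haustoria-formation genes: silent in both intact roots, strongly and
    # equally induced in both chimeras
    for _ in range(params.n_haustoria_genes):
        intact = rng.uniform(0.01, _FPKM_INTACT_MAX / 3.0, size=2)
        induced = max(
            float(_lognormal_means(rng, 1, params.base_abundance_log_mean, params.log_sd)[0]),
            fc * intact.max(),
            2.0 * _FPKM_MIN,
        )
        gm[idx] = (intact[0], induced, induced, intact[1])
        origin[idx] = "parasite_ref"
        truth.haustoria_genes.add(gene_ids[idx])
        idx += 1
    # correlated-pair genes: flat, high profile; the latent factor is applied
    # to the chimera replicates below
    pair_gene_ids = []
    for _ in range(params.n_correlated_pairs):
        m = float(_lognormal_means(rng, 1, params.base_abundance_log_mean, params.log_sd, floor=50.0)[0])
        gm[idx] = m
        origin[idx] = "parasite_ref"
        pair_gene_ids.append(gene_ids[idx])
        idx += 1
    # background: species-specific (own side high, other side low) or shared
    n_bg = params.n_genes - idx
    bg_shared = rng.random(n_bg) < 0.3
    bg_host = rng.random(n_bg) < 0.5
    exclude_band = (_FPKM_MIN / 2.0, 2.0 * _FPKM_MIN)
    bg_hi = _lognormal_means(
        rng, n_bg, params.base_abundance_log_mean, params.log_sd, exclude=exclude_band
    )
    bg_lo = lo_vals(n_bg)
    for j in range(n_bg):
        i = idx + j
        if bg_shared[j]:
            gm[i] = bg_hi[j]
            origin[i] = "host_ref" if bg_host[j] else "parasite_ref"
        elif bg_host[j]:
            gm[i] = (bg_lo[j], bg_lo[j], bg_hi[j], bg_hi[j])
            origin[i] = "host_ref"
        else:
            gm[i] = (bg_hi[j], bg_hi[j], bg_lo[j], bg_lo[j])
            origin[i] = "parasite_ref"
    truth.gene_origin = dict(zip(gene_ids, origin))

    # ----- metabolite compartment means -------------------------------
    metab_ids = [f"M{i:04d}" for i in range(1, params.n_metabolites + 1)]
    mm = np.zeros((params.n_metabolites, 4))
    dl = params.detection_limit
    detect_floor = 4.0 * dl if dl > 0 else None

    idx_m = 0
    # transferred metabolites share one mean across their three "present"
    # compartments, so the only differential signal is the planted absence
    for _ in range(params.n_transferred_host_to_parasite):
        m = float(_lognormal_means(rng, 1, params.metabolite_log_mean, params.log_sd, floor=detect_floor)[0])
        mm[idx_m] = (0.0, m, m, m)
        truth.transferred_metabolites[metab_ids[idx_m]] = "host_to_parasite"
        truth.dam_up["TH_vs_THC"].add(metab_ids[idx_m])
        idx_m += 1
    for _ in range(params.n_transferred_parasite_to_host):
        m = float(_lognormal_means(rng, 1, params.metabolite_log_mean, params.log_sd, floor=detect_floor)[0])
        mm[idx_m] = (m, m, m, 0.0)
        truth.transferred_metabolites[metab_ids[idx_m]] = "parasite_to_host"
        truth.dam_up["P_vs_PC"].add(metab_ids[idx_m])
        idx_m += 1
    # common differential metabolites: alternately up/up and down/down in the
    # two chimera-vs-intact comparisons
    down_floor = (detect_floor or 1.0) * fc
    for j in range(params.n_common_dams):
        m = float(_lognormal_means(rng, 1, params.metabolite_log_mean, params.log_sd, floor=down_floor)[0])
        if j % 2 == 0:
            mm[idx_m] = (m, fc * m, fc * m, m)
            truth.dam_up["TH_vs_THC"].add(metab_ids[idx_m])
            truth.dam_up["P_vs_PC"].add(metab_ids[idx_m])
        else:
            mm[idx_m] = (m, m / fc, m / fc, m)
            truth.dam_down["TH_vs_THC"].add(metab_ids[idx_m])
            truth.dam_down["P_vs_PC"].add(metab_ids[idx_m])
        idx_m += 1
    pair_metab_ids = []
    for _ in range(params.n_correlated_pairs):
        m = float(_lognormal_means(rng, 1, params.metabolite_log_mean, params.log_sd, floor=detect_floor)[0])
        mm[idx_m] = m
        pair_metab_ids.append(metab_ids[idx_m])
        idx_m += 1
    n_bg_m = params.n_metabolites - idx_m
    mm[idx_m:] = _lognormal_means(
        rng, n_bg_m, params.metabolite_log_mean, params.log_sd, floor=detect_floor
    )[:, None]

    # ----- replicate noise --------------------------------------------
    def noisy(means: np.ndarray) -> np.ndarray:
        comp_index = {c: k for k, c in enumerate(COMPARTMENTS)}
        base = means[:, [comp_index[c] for c in comp_of]]
        z = rng.normal(size=base.shape)
        return base * np.exp(sigma * z - sigma**2 / 2.0)

    gene_values = noisy(gm)
    metab_values = noisy(mm)

    # ----- latent factors for correlated pairs ------------------------
    s = params.latent_strength
    s_neg = min(s, 0.22)  # lognormal anti-correlation saturates near |r|=0.9
    n_chim = int(chimera_cols.sum())
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    metab_pos = {m: i for i, m in enumerate(metab_ids)}
    for j, (gid, mid) in enumerate(zip(pair_gene_ids, pair_metab_ids)):
        sign = "neg" if rng.random() < params.negative_pair_fraction else "pos"
        z = rng.normal(size=n_chim)
        sj = s if sign == "pos" else s_neg
        gfac = np.exp(sj * z - sj**2 / 2.0)
        mfac = np.exp((sj if sign == "pos" else -sj) * z - sj**2 / 2.0)
        gene_values[gene_pos[gid], chimera_cols] *= gfac
        metab_values[metab_pos[mid], chimera_cols] *= mfac
        truth.correlated_pairs.add((gid, mid, sign))

    # ----- metabolite detection censoring -----------------------------
    metab_values = metab_values.copy()
    metab_values[metab_values < dl] = np.nan

    gene_table = FeatureTable(
        frame=pd.DataFrame(gene_values, index=gene_ids, columns=sample_ids),
        sample_to_compartment=dict(sample_map),
        feature_kind="gene",
    )
    metab_table = FeatureTable(
        frame=pd.DataFrame(metab_values, index=metab_ids, columns=sample_ids),
        sample_to_compartment=dict(sample_map),
        feature_kind="metabolite",
    )

    # ----- genomes and unigenes ---------------------------------------
    alphabet = np.array(list("ACGT"))
    genomes = {
        "parasite_ref": "".join(rng.choice(alphabet, size=params.genome_length)),
        "host_ref": "".join(rng.choice(alphabet, size=params.genome_length)),
    }
    lo, hi = params.unigene_length
    unigenes = {}
    for gid in gene_ids:
        src = genomes[truth.gene_origin[gid]]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(src) - length + 1))
        unigenes[gid] = src[start : start + length]

    return gene_table, metab_table, genomes, unigenes, truth


def write_experiment(
    out_dir: str | Path,
    gene_table: FeatureTable,
    metab_table: FeatureTable,
    genomes: dict[str, str],
    unigenes: dict[str, str],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write an experiment to disk (tables, sample map, FASTAs, truth JSON)."""
    from .io_formats import write_fasta, write_feature_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "metabolites": out / "metabolites.tsv",
        "sample_map": out / "samples.tsv",
        "genome_parasite": out / "genome_parasite.fasta",
        "genome_host": out / "genome_host.fasta",
        "unigenes": out / "unigenes.fasta",
        "truth": out / "truth.json",
    }
    write_feature_table(gene_table, paths["genes"])
    write_feature_table(metab_table, paths["metabolites"])
    lines = [f"{s}\t{c}" for s, c in gene_table.sample_to_compartment.items()]
    paths["sample_map"].write_text("\n".join(lines) + "\n")
    write_fasta({"parasite_ref": genomes["parasite_ref"]}, paths["genome_parasite"])
    write_fasta({"host_ref": genomes["host_ref"]}, paths["genome_host"])
    write_fasta(unigenes, paths["unigenes"])
    truth.to_json(paths["truth"])
    return paths
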