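"""Haustoria-formation gene selection and the gene-metabolite network.

Candidate genes must be upregulated in both chimeras (Welch-test stand-in
predicate from :mod:`hausflow.dam_screen`) and near-silent (FPKM < 0.3) in
an intact compartment.  Selected genes are then correlated with selected
metabolites across shared samples; edges with |Pearson r| > 0.80 and
p < 0.05 (both strict) survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dam_screen import welch_upregulation
from .io_formats import COMPARTMENTS, FeatureTable

__all__ = [
    "HaustoriaGeneCall",
    "NetworkEdge",
    "common_chimera_genes",
    "select_haustoria_genes",
    "pearson_network",
]


@dataclass(frozen=True)
class HaustoriaGeneCall:
    """Selection record for one candidate haustoria-formation gene."""

    feature_id: str
    fpkm_means: tuple[float, float, float, float]  # (TH, THC, PC, P)
    upregulated_thc: bool
    upregulated_pc: bool
    intact_min_fpkm: float  # the intact-side statistic the predicate used
    qualifies: bool


@dataclass(frozen=True)
class NetworkEdge:
    """A retained gene-metabolite correlation."""

    gene_id: str
    metabolite_id: str
    pcc: float
    p_value: float
    sign: str  # "pos" | "neg"


def common_chimera_genes(thc_ids: Iterable[str], pc_ids: Iterable[str]) -> list[str]:
    """Intersection of the two chimera gene sets, lexicographically ordered."""
    return sorted(set(thc_ids) & set(pc_ids))


def select_haustoria_genes(
    genes: FeatureTable,
    fpkm_intact_max: float = 0.3,
    intact_mode: str = "any",
    fc_min: float = 1.0,
    q_max: float = 0.05,
    candidate_ids: Sequence[str] | None = None,
    aggregation: str = "mean",
) -> list[HaustoriaGeneCall]:
    """Score every candidate gene for haustoria-formation association.

    A gene qualifies when it is upregulated in both chimeras (THC vs TH and
    PC vs P, log2FC >= ``fc_min`` with BH q < ``q_max``) and its intact-root
    expression satisfies the intact predicate: with ``intact_mode="any"``
    min(TH, P) < ``fpkm_intact_max``; with ``"both"`` max(TH, P) <
    ``fpkm_intact_max``.
    """
    if intact_mode not in ("any", "both"):
        raise ValueError(f"unknown intact_mode {intact_mode!r}")
    genes.require_compartments(COMPARTMENTS)
    if genes.n_features == 0:
        return []
    up_thc = welch_upregulation(genes, ("TH", "THC"), fc_min=fc_min, q_max=q_max)
    up_pc = welch_upregulation(genes, ("P", "PC"), fc_min=fc_min, q_max=q_max)
    means = genes.compartment_means(aggregation=aggregation, missing_as_zero=True)

    ids = list(candidate_ids) if candidate_ids is not None else genes.feature_ids
    calls = []
    for fid in ids:
        th, thc, pc, p = (float(means.loc[fid, c]) for c in COMPARTMENTS)
        intact_stat = min(th, p) if intact_mode == "any" else max(th, p)
        u_thc = bool(up_thc.loc[fid, "up"])
        u_pc = bool(up_pc.loc[fid, "up"])
        calls.append(
            HaustoriaGeneCall(
                feature_id=fid,
                fpkm_means=(th, thc, pc, p),
                upregulated_thc=u_thc,
                upregulated_pc=u_pc,
                intact_min_fpkm=intact_stat,
                qualifies=u_thc and u_pc and intact_stat < fpkm_intact_max,
            )
        )
    return calls


def _pearson_p(r: float, n: int) -> float:
    """Two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    if abs(r) >= 1.0:
        return float(np.nextafter(0.0, 1.0))
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def pearson_network(
    gene_expr: FeatureTable,
    metab: FeatureTable,
    samples: Sequence[str] | None = None,
    pcc_min: float = 0.80,
    p_max: float = 0.05,
    bh_adjust: bool = False,
) -> list[NetworkEdge]:
    """Correlate every gene with every metabolite across shared samples.

    ``samples`` defaults to the chimera samples (THC + PC) present in both
    tables, since haustoria-formation features are defined on the chimeras.
    Pairs are correlated over their pairwise-complete observations; constant
    vectors are skipped with a warning.  Retains strictly |r| > ``pcc_min``
    and p < ``p_max`` (optionally BH-adjusted p).
    """
    if samples is None:
        shared = [s for s in gene_expr.sample_ids if s in set(metab.sample_ids)]
        samples = [
            s for s in shared if gene_expr.sample_to_compartment[s] in ("THC", "PC")
        ]
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("pearson_network needs >= 3 shared samples")

    g = gene_expr.frame[samples]
    m = metab.frame[samples]
    candidates: list[tuple[str, str, float, float]] = []
    for gid in gene_expr.feature_ids:
        gv = g.loc[gid].to_numpy()
        for mid in metab.feature_ids:
            mv = m.loc[mid].to_numpy()
            ok = np.isfinite(gv) & np.isfinite(mv)
            if ok.sum() < 3:
                warnings.warn(
                    f"pair ({gid}, {mid}) has fewer than 3 complete samples; skipped",
                    stacklevel=2,
                )
                continue
            x, y = gv[ok], mv[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant vector in pair ({gid}, {mid}); skipped", stacklevel=2
                )
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            p = _pearson_p(r, len(x))
            candidates.append((gid, mid, r, p))

    if bh_adjust and candidates:
        qs = multipletests([c[3] for c in candidates], method="fdr_bh")[1]
        candidates = [(g_, m_, r, float(q)) for (g_, m_, r, _), q in zip(candidates, qs)]

    edges = [
        NetworkEdge(gid, mid, r, p, "pos" if r > 0 else "neg")
        for gid, mid, r, p in candidates
        if abs(r) > pcc_min and p < p_max
    ]
    edges.sort(key=lambda e: (e.gene_id, e.metabolite_id))
    return edges
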