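"""Differential-abundance screening.

Implements the two-compartment screen used for metabolite tables: group-mean
log2 fold change combined with a variable-importance-in-projection (VIP)
score from an OPLS-DA model.  A feature is called differentially accumulated
when VIP >= 1 and |log2FC| >= 1 (both boundaries inclusive).  Also houses the
PCA quality check, cross-comparison co-regulation classes, hypergeometric
enrichment, and the Welch-test upregulation predicate used as a documented
stand-in where a count-based differential-expression caller is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import FeatureTable

__all__ = [
    "DamRecord",
    "OplsModel",
    "CoRegulationRecord",
    "PcaResult",
    "EnrichmentRecord",
    "log2_fold_change",
    "default_pseudo",
    "fit_opls_da",
    "vip_scores",
    "screen_dams",
    "coregulation_classes",
    "pca_qc",
    "hypergeometric_enrichment",
    "welch_upregulation",
]


@dataclass(frozen=True)
class DamRecord:
    """One feature's differential call for one (reference, test) comparison."""

    feature_id: str
    comparison: tuple[str, str]
    log2fc: float
    vip: float
    regulation: str  # "up" | "down" | "not_significant"


@dataclass(frozen=True)
class CoRegulationRecord:
    """Regulation-type pair for a feature differential in both comparisons."""

    feature_id: str
    type_pair: tuple[str, str]  # (regulation in comparison A, in comparison B)


@dataclass
class OplsModel:
    """Fitted OPLS-DA model with one predictive component.

    All vectors are over the retained (non-constant) features, in
    ``feature_ids`` order.  Scaling is centering + unit variance.
    """

    feature_ids: list[str]
    excluded_features: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    weights: np.ndarray  # unit-norm predictive weight vector w
    scores: np.ndarray  # predictive scores t (per sample)
    loadings: np.ndarray  # predictive loadings p
    y_loading: float  # q
    orthogonal_weights: list[np.ndarray] = field(default_factory=list)
    orthogonal_scores: list[np.ndarray] = field(default_factory=list)
    orthogonal_loadings: list[np.ndarray] = field(default_factory=list)
    ssy_explained: list[float] = field(default_factory=list)  # per predictive comp.
    r2y: float = 0.0
    sample_ids: list[str] = field(default_factory=list)


def default_pseudo(table: FeatureTable) -> float:
    """Half the smallest nonzero abundance in the table (1.0 if none)."""
    vals = table.frame.to_numpy().ravel()
    vals = vals[np.isfinite(vals) & (vals > 0)]
    return float(vals.min()) / 2.0 if vals.size else 1.0


def log2_fold_change(mean_ref: float, mean_test: float, pseudo: float) -> float:
    """log2((mean_test + pseudo) / (mean_ref + pseudo)) on group means."""
    if mean_ref < 0 or mean_test < 0:
        raise ValueError("group means must be non-negative")
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    return math.log2((mean_test + pseudo) / (mean_ref + pseudo))


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _as_matrix(X, y) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Coerce input to (samples x features, centered y) with id lists."""
    if isinstance(X, FeatureTable):
        frame = X.frame.fillna(0.0)
        feature_ids = list(frame.index)
        sample_ids = list(frame.columns)
        mat = frame.to_numpy().T
    elif isinstance(X, pd.DataFrame):
        feature_ids = list(X.index)
        sample_ids = list(X.columns)
        mat = X.fillna(0.0).to_numpy().T
    else:
        mat = np.asarray(X, dtype=float).T  # features x samples in, transpose
        feature_ids = [f"f{i}" for i in range(mat.shape[1])]
        sample_ids = [f"s{i}" for i in range(mat.shape[0])]
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != mat.shape[0]:
        raise ValueError("y length must equal the number of samples")
    return mat, yv, feature_ids, sample_ids


def fit_opls_da(X, y, n_orthogonal: int = 1) -> OplsModel:
    """Fit an OPLS-DA model: ``n_orthogonal`` y-orthogonal components are
    stripped from X before a single predictive PLS component is extracted.

    ``X`` is features x samples (array, DataFrame or FeatureTable); ``y`` is a
    +/-1 class vector.  Features are centered and unit-variance scaled;
    zero-variance features are excluded with a warning.  The single-response
    fit is closed-form, hence fully deterministic.
    """
    mat, yv, feature_ids, sample_ids = _as_matrix(X, y)
    n_samples = mat.shape[0]
    classes = np.unique(yv)
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    for c in classes:
        if (yv == c).sum() < 2:
            raise ValueError("need >= 2 samples per class")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    if n_orthogonal > n_samples - 2:
        raise ValueError(
            f"n_orthogonal = {n_orthogonal} exceeds n_samples - 2 = {n_samples - 2}"
        )

    sd = mat.std(axis=0, ddof=1)
    keep = sd > 0
    excluded = [fid for fid, k in zip(feature_ids, keep) if not k]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance feature(s) from OPLS-DA",
            stacklevel=2,
        )
    kept_ids = [fid for fid, k in zip(feature_ids, keep) if k]
    if not kept_ids:
        raise ValueError("no non-constant features to fit")
    x_mean = mat[:, keep].mean(axis=0)
    x_scale = sd[keep]
    Xs = (mat[:, keep] - x_mean) / x_scale
    yc = yv - yv.mean()
    ss_y = float(yc @ yc)

    # Predictive weight direction; unchanged by orthogonal deflation because
    # each orthogonal score is orthogonal to y by construction.
    w = Xs.T @ yc
    norm_w = np.linalg.norm(w)
    if norm_w == 0:
        raise ValueError("X carries no covariance with y")
    w = w / norm_w

    Xd = Xs.copy()
    orth_w: list[np.ndarray] = []
    orth_t: list[np.ndarray] = []
    orth_p: list[np.ndarray] = []
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm_wo = np.linalg.norm(wo)
        if norm_wo < 1e-12:
            break  # no structured orthogonal variation left
        wo = wo / norm_wo
        to = Xd @ wo
        po = Xd.T @ to / (to @ to)
        Xd = Xd - np.outer(to, po)
        orth_w.append(wo)
        orth_t.append(to)
        orth_p.append(po)

    t = Xd @ w
    tt = float(t @ t)
    p = Xd.T @ t / tt
    q = float(yc @ t) / tt
    ssy_expl = q * q * tt  # sum of squares of y captured by the component
    resid = yc - t * q
    r2y = 1.0 - float(resid @ resid) / ss_y if ss_y > 0 else 0.0

    return OplsModel(
        feature_ids=kept_ids,
        excluded_features=excluded,
        x_mean=x_mean,
        x_scale=x_scale,
        weights=w,
        scores=t,
        loadings=p,
        y_loading=q,
        orthogonal_weights=orth_w,
        orthogonal_scores=orth_t,
        orthogonal_loadings=orth_p,
        ssy_explained=[ssy_expl],
        r2y=r2y,
        sample_ids=sample_ids,
    )


def vip_scores(model: OplsModel, include_orthogonal: bool = False) -> dict[str, float]:
    """VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a) over unit-norm
    weight vectors; mean(VIP^2) over features is exactly 1.

    By default only the predictive component contributes (orthogonal
    components are class-uncorrelated by construction); ``include_orthogonal``
    adds them weighted by their — essentially zero — explained y variance.
    """
    comps: list[tuple[np.ndarray, float]] = [(model.weights, model.ssy_explained[0])]
    if include_orthogonal:
        for wo, to in zip(model.orthogonal_weights, model.orthogonal_scores):
            comps.append((wo, 0.0))
    p = len(model.feature_ids)
    total = sum(s for _, s in comps)
    if total <= 0:
        return {fid: 0.0 for fid in model.feature_ids}
    acc = np.zeros(p)
    for w, s in comps:
        acc += s * w**2
    vips = np.sqrt(p * acc / total)
    return dict(zip(model.feature_ids, vips))


# ---------------------------------------------------------------------------
# DAM calls
# ---------------------------------------------------------------------------


def screen_dams(
    table: FeatureTable,
    comparison: tuple[str, str],
    vip_min: float = 1.0,
    fc_min: float = 1.0,
    pseudo: float | None = None,
    n_orthogonal: int = 1,
    aggregation: str = "mean",
) -> list[DamRecord]:
    """Call differential features between two compartments.

    ``comparison`` is (reference_compartment, test_compartment).  Missing
    cells count as 0 for group means; a feature is "up" when
    log2FC >= fc_min and VIP >= vip_min, "down" when log2FC <= -fc_min and
    VIP >= vip_min (boundaries inclusive).
    """
    ref, test = comparison
    table.require_compartments([ref, test])
    if table.n_features == 0:
        return []
    pseudo = default_pseudo(table) if pseudo is None else pseudo

    samples = table.samples_in(ref) + table.samples_in(test)
    sub = table.subset_samples(samples)
    y = np.array([-1.0 if table.sample_to_compartment[s] == ref else 1.0 for s in samples])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance exclusions reported via VIP=0
        model = fit_opls_da(sub.frame, y, n_orthogonal=n_orthogonal)
    vips = vip_scores(model)

    means = table.compartment_means(aggregation=aggregation, missing_as_zero=True)
    records = []
    for fid in table.feature_ids:
        lfc = log2_fold_change(float(means.loc[fid, ref]), float(means.loc[fid, test]), pseudo)
        vip = vips.get(fid, 0.0)  # constant features carry no projection weight
        if lfc >= fc_min and vip >= vip_min:
            reg = "up"
        elif lfc <= -fc_min and vip >= vip_min:
            reg = "down"
        else:
            reg = "not_significant"
        records.append(
            DamRecord(feature_id=fid, comparison=(ref, test), log2fc=lfc, vip=vip, regulation=reg)
        )
    return records


def coregulation_classes(
    dams_a: Iterable[DamRecord], dams_b: Iterable[DamRecord]
) -> list[CoRegulationRecord]:
    """Intersect two screens: features differential in both comparisons, with
    their (regulation_a, regulation_b) type pair.  Output is id-sorted."""
    sig_a = {r.feature_id: r.regulation for r in dams_a if r.regulation != "not_significant"}
    sig_b = {r.feature_id: r.regulation for r in dams_b if r.regulation != "not_significant"}
    common = sorted(set(sig_a) & set(sig_b))
    return [CoRegulationRecord(fid, (sig_a[fid], sig_b[fid])) for fid in common]


# ---------------------------------------------------------------------------
# PCA quality check
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # features x components (retained features)
    feature_ids: list[str]


def pca_qc(table: FeatureTable, n_components: int | None = None) -> PcaResult:
    """Centered, unit-variance-scaled PCA of samples.

    Deterministic sign convention: in each component the largest-|loading|
    feature gets a positive loading.  Missing cells count as 0; constant
    features are dropped (they carry no variance).
    """
    if len(table.sample_ids) < 3:
        raise ValueError("PCA needs >= 3 samples")
    mat = table.frame.fillna(0.0).to_numpy().T  # samples x features
    sd = mat.std(axis=0, ddof=1)
    keep = sd > 0
    feature_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    X = (mat[:, keep] - mat[:, keep].mean(axis=0)) / sd[keep]
    n_samples = X.shape[0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S.max(initial=0) * 1e-12).sum()) if S.size else 0
    k = rank if n_components is None else min(n_components, rank)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * S
    var = S**2 / (n_samples - 1)
    total_var = X.var(axis=0, ddof=1).sum()
    ratio = var / total_var if total_var > 0 else np.zeros_like(var)
    return PcaResult(
        sample_ids=table.sample_ids,
        scores=scores,
        explained_variance_ratio=ratio,
        loadings=Vt.T,
        feature_ids=feature_ids,
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    n_term_universe: int  # K
    n_term_selected: int  # k
    p_value: float
    q_value: float
    empty_term: bool  # K == 0 in the universe


def hypergeometric_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentRecord]:
    """Exact upper-tail hypergeometric enrichment, BH-adjusted across terms.

    p = P(X >= k) for a draw of n = |selected| from N = |universe| containing
    K = |term ∩ universe| successes.  Terms absent from the universe get
    p = 1 and are flagged.
    """
    sel = set(selected)
    uni = set(universe)
    if not sel <= uni:
        raise ValueError("selected must be a subset of universe")
    N, n = len(uni), len(sel)
    terms = sorted(term_map)
    ps = []
    rows = []
    for term in terms:
        members = set(term_map[term]) & uni
        K = len(members)
        k = len(members & sel)
        if K == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ps.append(min(p, 1.0))
        rows.append((term, K, k))
    qs = multipletests(ps, method="fdr_bh")[1] if ps else []
    return [
        EnrichmentRecord(term, K, k, p, float(q), K == 0)
        for (term, K, k), p, q in zip(rows, ps, qs)
    ]


# ---------------------------------------------------------------------------
# Welch-test upregulation predicate (documented stand-in for a count-based
# differential-expression caller, which is out of scope)
# ---------------------------------------------------------------------------


def welch_upregulation(
    table: FeatureTable,
    comparison: tuple[str, str],
    fc_min: float = 1.0,
    q_max: float = 0.05,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Per-feature upregulation call: group-mean log2FC >= fc_min and Welch
    t-test (on log2(x + pseudo) replicate values) BH-adjusted q < q_max,
    test compartment vs reference.

    Returns a DataFrame indexed by feature id with columns ``log2fc``, ``p``,
    ``q`` and boolean ``up``.
    """
    ref, test = comparison
    table.require_compartments([ref, test])
    pseudo = default_pseudo(table) if pseudo is None else pseudo
    if table.n_features == 0:
        return pd.DataFrame(columns=["log2fc", "p", "q", "up"])

    a = table.frame[table.samples_in(ref)].fillna(0.0).to_numpy()
    b = table.frame[table.samples_in(test)].fillna(0.0).to_numpy()
    lfc = np.array(
        [log2_fold_change(ma, mb, pseudo) for ma, mb in zip(a.mean(axis=1), b.mean(axis=1))]
    )
    # test on the log scale: replicate noise is multiplicative, and at n = 3
    # a raw-scale test has almost no power against the BH correction
    la, lb = np.log2(a + pseudo), np.log2(b + pseudo)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.ttest_ind(lb, la, axis=1, equal_var=False).pvalue
    # degenerate rows: both groups constant -> 1 if equal means else 0
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        pvals = np.where(degenerate, np.where(equal, 1.0, 0.0), pvals)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    up = (lfc >= fc_min) & (qvals < q_max)
    return pd.DataFrame(
        {"log2fc": lfc, "p": pvals, "q": qvals, "up": up}, index=table.feature_ids
    )
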