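"""Assign unigenes to the parasite or host reference genome.

Two routes share one decision rule: an external tabular-alignment route
(best bitscore per genome, pre-filtered by e-value) and a built-in canonical
k-mer containment classifier for desk-scale runs without an aligner.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import OriginHit

PARASITE = "parasite_ref"
HOST = "host_ref"

__all__ = ["PARASITE", "HOST", "OriginCall", "assign_from_hits", "kmer_assign"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class OriginCall:
    """Genome assignment for one unigene.

    ``score`` is the winning bitscore (alignment route) or canonical k-mer
    containment fraction in [0, 1] (k-mer route); ``margin`` is best minus
    second-best (second-best taken as 0 when only one genome is hit).
    """

    query_id: str
    assigned_genome: str  # PARASITE | HOST | "ambiguous" | "unassigned"
    score: float
    margin: float


def assign_from_hits(
    hits: Iterable[OriginHit],
    tie_tol: float = 1e-6,
    query_ids: Iterable[str] | None = None,
) -> list[OriginCall]:
    """Assign each query to the genome holding its best hit.

    Per query and genome the best hit is the highest bitscore (ties broken by
    lower e-value, then subject id lexicographic).  The query is assigned to
    the genome with the higher best bitscore; ``ambiguous`` when both genomes
    are hit and the bitscore gap is below ``tie_tol``.  ``query_ids``
    optionally forces an ``unassigned`` call for queries with no hit.
    """
    by_query: dict[str, list[OriginHit]] = defaultdict(list)
    for hit in hits:
        by_query[hit.query_id].append(hit)

    all_queries = sorted(set(by_query) | set(query_ids or ()))
    calls = []
    for query in all_queries:
        qhits = by_query.get(query)
        if not qhits:
            calls.append(OriginCall(query, "unassigned", 0.0, 0.0))
            continue
        best: dict[str, OriginHit] = {}
        for hit in qhits:
            cur = best.get(hit.subject_genome)
            if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < (
                -cur.bitscore,
                cur.evalue,
                cur.subject_id,
            ):
                best[hit.subject_genome] = hit
        score_p = best[PARASITE].bitscore if PARASITE in best else None
        score_h = best[HOST].bitscore if HOST in best else None
        if score_p is not None and score_h is not None:
            margin = abs(score_p - score_h)
            if margin < tie_tol:
                calls.append(OriginCall(query, "ambiguous", max(score_p, score_h), margin))
            else:
                genome = PARASITE if score_p > score_h else HOST
                calls.append(OriginCall(query, genome, max(score_p, score_h), margin))
        else:
            genome = PARASITE if score_p is not None else HOST
            score = score_p if score_p is not None else score_h
            calls.append(OriginCall(query, genome, score, score))
    return calls


def _canonical_kmers(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue  # masked/ambiguous bases break the k-mer
        rc = kmer.translate(_COMPLEMENT)[::-1]
        out.add(min(kmer, rc))
    return out


def kmer_assign(
    unigenes: Mapping[str, str],
    genome_a: str,
    genome_b: str,
    k: int = 21,
    labels: tuple[str, str] = (PARASITE, HOST),
    min_score: float = 0.5,
    tie_tol: float = 1e-6,
) -> list[OriginCall]:
    """Assign unigenes by canonical k-mer containment against two genomes.

    The score against a genome is the fraction of the query's canonical
    (strand-collapsed) k-mers present in that genome's k-mer set, which makes
    the classifier invariant to query orientation.  A query whose best score
    is below ``min_score`` (or that is shorter than ``k``) is ``unassigned``;
    one where both genomes pass ``min_score`` within ``tie_tol`` is
    ``ambiguous``.
    """
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError("k must be odd and within [11, 31]")
    set_a = _canonical_kmers(genome_a, k)
    set_b = _canonical_kmers(genome_b, k)
    label_a, label_b = labels

    calls = []
    for query in sorted(unigenes):
        kmers = _canonical_kmers(unigenes[query], k)
        if not kmers:
            warnings.warn(f"query {query!r} shorter than k={k} or fully masked", stacklevel=2)
            calls.append(OriginCall(query, "unassigned", 0.0, 0.0))
            continue
        score_a = len(kmers & set_a) / len(kmers)
        score_b = len(kmers & set_b) / len(kmers)
        best = max(score_a, score_b)
        margin = abs(score_a - score_b)
        if best < min_score:
            calls.append(OriginCall(query, "unassigned", best, margin))
        elif min(score_a, score_b) >= min_score and margin < tie_tol:
            calls.append(OriginCall(query, "ambiguous", best, margin))
        else:
            genome = label_a if score_a > score_b else label_b
            calls.append(OriginCall(query, genome, best, margin))
    return calls
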