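"""Direction-classified transfer calls from four-compartment patterns.

Metabolites: a compound undetected in exactly one intact compartment (TH or
P) but detected in the other three is a transferred metabolite, with the
direction implied by which intact compartment lacks it.  Genes: the same
logic on replicate-mean FPKM against a presence threshold (default 3,
inclusive), optionally restricted to unigenes with an unambiguous genome
origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .io_formats import COMPARTMENTS, FeatureTable
from .origin_assign import OriginCall

__all__ = [
    "TransferCall",
    "MobilityCall",
    "direction_from_pattern",
    "classify_transfer",
    "detect_mobile_genes",
]

HOST_TO_PARASITE = "host_to_parasite"
PARASITE_TO_HOST = "parasite_to_host"
TH_TO_P = "th_to_p"
P_TO_TH = "p_to_th"
NONE = "none"


@dataclass(frozen=True)
class TransferCall:
    """Transfer direction for one metabolite with its evidence pattern.

    ``presence_pattern`` is (TH, THC, PC, P); ``intensities`` holds the mean
    detected intensity per compartment (None where nothing was detected).
    """

    feature_id: str
    direction: str  # HOST_TO_PARASITE | PARASITE_TO_HOST | NONE
    presence_pattern: tuple[bool, bool, bool, bool]
    intensities: tuple[Optional[float], Optional[float], Optional[float], Optional[float]]


@dataclass(frozen=True)
class MobilityCall:
    """Mobility direction for one gene from its compartment FPKM means."""

    feature_id: str
    direction: str  # TH_TO_P | P_TO_TH | NONE
    fpkm_means: tuple[float, float, float, float]  # (TH, THC, PC, P)
    origin: Optional[OriginCall] = None


def direction_from_pattern(pattern: tuple[bool, bool, bool, bool]) -> str:
    """Map a (TH, THC, PC, P) presence pattern to a transfer direction.

    Exactly two of the 16 patterns are directional: absent only in the intact
    parasite root (host -> parasite) or only in the intact host root
    (parasite -> host).
    """
    if pattern == (False, True, True, True):
        return HOST_TO_PARASITE
    if pattern == (True, True, True, False):
        return PARASITE_TO_HOST
    return NONE


def classify_transfer(
    metabolites: FeatureTable,
    detection_limit: float = 0.0,
    min_detect_reps: int | None = None,
) -> list[TransferCall]:
    """Classify every metabolite's transfer direction.

    A compartment counts as "present" when the metabolite is detected
    (non-missing and > ``detection_limit``) in at least ``min_detect_reps``
    of its replicates — by default in all of them, which makes absence calls
    conservative.  All four compartments must have samples.
    """
    metabolites.require_compartments(COMPARTMENTS)
    comp_samples = {c: metabolites.samples_in(c) for c in COMPARTMENTS}

    calls = []
    for fid in metabolites.feature_ids:
        row = metabolites.frame.loc[fid]
        pattern = []
        intensities = []
        for comp in COMPARTMENTS:
            vals = row[comp_samples[comp]].to_numpy()
            detected = np.isfinite(vals) & (vals > detection_limit)
            need = len(vals) if min_detect_reps is None else min(min_detect_reps, len(vals))
            pattern.append(bool(detected.sum() >= need))
            intensities.append(float(vals[detected].mean()) if detected.any() else None)
        pattern = tuple(pattern)
        calls.append(
            TransferCall(
                feature_id=fid,
                direction=direction_from_pattern(pattern),
                presence_pattern=pattern,
                intensities=tuple(intensities),
            )
        )
    return calls


def detect_mobile_genes(
    genes: FeatureTable,
    fpkm_min: float = 3.0,
    origin_calls: Iterable[OriginCall] | Mapping[str, OriginCall] | None = None,
    aggregation: str = "mean",
) -> list[MobilityCall]:
    """Classify mobile genes from compartment FPKM means.

    A gene moves parasite -> host (``th_to_p``) when its mean FPKM is below
    ``fpkm_min`` in the intact host root P but at or above it in TH, THC and
    PC; ``p_to_th`` is the mirror image (boundary values count as present).
    Genes whose origin call is ambiguous or unassigned are excluded first
    when ``origin_calls`` is given.
    """
    genes.require_compartments(COMPARTMENTS)
    origin_map: dict[str, OriginCall] = {}
    if origin_calls is not None:
        if isinstance(origin_calls, Mapping):
            origin_map = dict(origin_calls)
        else:
            origin_map = {c.query_id: c for c in origin_calls}

    means = genes.compartment_means(aggregation=aggregation, missing_as_zero=True)
    calls = []
    for fid in genes.feature_ids:
        origin = origin_map.get(fid)
        if origin is not None and origin.assigned_genome in ("ambiguous", "unassigned"):
            continue
        th, thc, pc, p = (float(means.loc[fid, c]) for c in COMPARTMENTS)
        if p < fpkm_min and min(th, thc, pc) >= fpkm_min:
            direction = TH_TO_P
        elif th < fpkm_min and min(thc, pc, p) >= fpkm_min:
            direction = P_TO_TH
        else:
            direction = NONE
        calls.append(
            MobilityCall(feature_id=fid, direction=direction, fpkm_means=(th, thc, pc, p), origin=origin)
        )
    return calls
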