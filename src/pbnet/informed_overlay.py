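"""The "informed" layers on top of the molecular network.

Node-level context that turns a bare similarity graph into an interpretable
map: a 420 nm absorbance flag (all known phylloxanthobilins absorb near
420 nm), a retention-time border weight (hydrophobicity proxy), per-fraction
intensity pie shares, ordinal antioxidant-activity classes per fraction
(FRAP: inactive/active/very active/highly active) and an intensity-weighted
activity score that drives cluster prioritization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ms_io import DADTrace, FeatureRecord
from .network_builder import MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "UVParams",
    "BioactivityTable",
    "NodeOverlay",
    "ClusterRank",
    "ACTIVITY_CLASSES",
    "assign_uv",
    "rt_border",
    "classify_frap",
    "node_pie",
    "activity_score",
    "prioritize_clusters",
]

#: ordinal activity classes and their conventional colours
ACTIVITY_CLASSES = {0: "inactive", 1: "active", 2: "very_active", 3: "highly_active"}


@dataclass(frozen=True)
class UVParams:
    """Absorbance-filter parameters.

    ``threshold=None`` resolves at run time to 5× the trace median, a robust
    floor above baseline. ``rt_offset`` (signed, minutes) compensates the
    detector-to-MS plumbing delay; the default 0 assumes aligned clocks.
    """

    wavelength: float = 420.0
    rt_window: float = 0.1
    threshold: float | None = None
    rt_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.rt_window <= 0:
            raise ValueError("rt_window must be positive")


@dataclass(frozen=True)
class BioactivityTable:
    """Per-fraction assay readout: raw values and/or ordinal classes (0–3)."""

    raw: Mapping[str, float] = field(default_factory=dict)
    classes: Mapping[str, int] = field(default_factory=dict)
    assay: str = "FRAP"

    def __post_init__(self) -> None:
        if any(c not in ACTIVITY_CLASSES for c in self.classes.values()):
            raise ValueError("activity classes must be integers 0..3")


@dataclass(frozen=True)
class NodeOverlay:
    """Derived visual attributes for one node."""

    uv420_flag: bool = False
    absorbance: float = 0.0
    border_weight: float = 0.5
    pie_shares: Mapping[str, float] = field(default_factory=dict)
    activity_score: float | None = None


@dataclass(frozen=True)
class ClusterRank:
    """One connected component with its prioritization statistics."""

    rank: int
    node_ids: tuple[str, ...]
    n_active_nodes: int
    mean_score: float
    size: int
    n_uv_flagged: int


def assign_uv(
    features: Iterable[FeatureRecord], trace: DADTrace, params: UVParams = UVParams()
) -> dict[str, tuple[float, bool]]:
    """Per-feature (absorbance, flag): max trace value in an RT window.

    Features eluting outside the trace span get absorbance 0 and no flag,
    with a warning.
    """
    if trace.wavelength != params.wavelength:
        raise ValueError(
            f"trace wavelength {trace.wavelength} nm does not match filter wavelength {params.wavelength} nm"
        )
    threshold = params.threshold
    if threshold is None:
        threshold = 5.0 * float(np.median(trace.absorbance)) if len(trace) else 0.0
    out: dict[str, tuple[float, bool]] = {}
    t_min = float(trace.times.min()) if len(trace) else np.inf
    t_max = float(trace.times.max()) if len(trace) else -np.inf
    for f in features:
        center = f.rt + params.rt_offset
        if center < t_min - params.rt_window or center > t_max + params.rt_window:
            logger.warning("feature %s RT %.2f min outside DAD trace span", f.feature_id, f.rt)
            out[f.feature_id] = (0.0, False)
            continue
        absorbance = trace.window_max(center - params.rt_window, center + params.rt_window)
        out[f.feature_id] = (absorbance, absorbance >= threshold)
    return out


def rt_border(features: Iterable[FeatureRecord]) -> dict[str, float]:
    """Min-max scale retention times to [0, 1] border weights.

    Thicker borders mean later elution and thus greater hydrophobicity on a
    C18 reversed-phase column. All-equal RTs degenerate to 0.5 everywhere.
    """
    feats = list(features)
    if not feats:
        return {}
    rts = np.array([f.rt for f in feats])
    span = rts.max() - rts.min()
    if span == 0:
        return {f.feature_id: 0.5 for f in feats}
    return {f.feature_id: float((f.rt - rts.min()) / span) for f in feats}


def classify_frap(
    table: BioactivityTable, thresholds: Sequence[float] | None = None
) -> dict[str, int]:
    """Bin raw assay values into the four ordinal classes.

    Pre-assigned classes pass through unchanged (the published class list is
    only reproducible this way — the underlying cut points are empirical).
    Raw values need three ascending cut points; value < cut[0] → 0, ….
    """
    out: dict[str, int] = dict(table.classes)
    remaining = {f: v for f, v in table.raw.items() if f not in out}
    if remaining:
        if thresholds is None:
            raise ValueError("raw bioactivity values require three ascending cut points")
        cuts = list(thresholds)
        if len(cuts) != 3 or sorted(cuts) != cuts or len(set(cuts)) != 3:
            raise ValueError("thresholds must be three strictly ascending cut points")
        for frac, val in remaining.items():
            out[frac] = int(np.searchsorted(cuts, val, side="left"))
    return out


def node_pie(feature: FeatureRecord) -> dict[str, float]:
    """Fraction-wise intensity shares; all-zero intensity gives a zero vector."""
    total = feature.total_intensity
    if total <= 0:
        return {frac: 0.0 for frac in feature.intensities}
    return {frac: v / total for frac, v in feature.intensities.items()}


def activity_score(pie_shares: Mapping[str, float], classes: Mapping[str, int]) -> float:
    """Intensity-weighted mean activity class in [0, 3]."""
    return float(sum(share * classes.get(frac, 0) for frac, share in pie_shares.items()))


def prioritize_clusters(
    network: MolecularNetwork,
    overlays: Mapping[str, NodeOverlay],
    min_score: float = 2.5,
    min_active_nodes: int = 1,
) -> list[ClusterRank]:
    """Rank molecular families by their bioactive-node content.

    Sort key: count of nodes with activity score ≥ ``min_score`` (desc),
    then mean score (desc), then component size (desc); the UV-flag count is
    reported alongside. Components below ``min_active_nodes`` still appear,
    ranked by the same key.
    """
    ranked = []
    for comp in network.components():
        scores = [
            overlays[nid].activity_score
            for nid in comp
            if nid in overlays and overlays[nid].activity_score is not None
        ]
        n_active = sum(1 for s in scores if s >= min_score)
        mean_score = float(np.mean(scores)) if scores else 0.0
        n_uv = sum(1 for nid in comp if nid in overlays and overlays[nid].uv420_flag)
        ranked.append((n_active, mean_score, len(comp), n_uv, tuple(sorted(comp))))
    ranked.sort(key=lambda r: (-r[0], -r[1], -r[2], r[4]))
    return [
        ClusterRank(
            rank=i + 1,
            node_ids=nodes,
            n_active_nodes=n_active,
            mean_score=mean,
            size=size,
            n_uv_flagged=n_uv,
        )
        for i, (n_active, mean, size, n_uv, nodes) in enumerate(ranked)
    ]
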