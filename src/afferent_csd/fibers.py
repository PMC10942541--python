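"""Grouping ROIs into putative single-afferent fibers.

ROIs that belong to the same axon fire together: their fluorescence events
co-occur during quiet wakefulness.  The pipeline builds a per-ROI binary
event-indicator series restricted to quiet samples, computes the pairwise
Pearson correlation, thresholds it at 0.7 to form an adjacency matrix, and
clusters ROIs by the cosine dissimilarity between adjacency rows
(average-linkage agglomerative clustering).

The flat cut is made at cophenetic distance ``cutoff`` (default 0.75).  On
the [0, 1] range that binary adjacency rows produce, identical co-activation
patterns sit near 0 and unrelated ROIs near 1, so a mid-range cut separates
fibers while tolerating noisy single-event discrepancies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .session import FiberMap, RecordingSession
from .signals import EventTrain, StandardizedTrace

__all__ = ["CorrelationGraph", "event_correlation", "cluster_fibers", "fiber_trace"]


@dataclass
class CorrelationGraph:
    corr: np.ndarray           # Pearson correlation of quiet event indicators
    adjacency: np.ndarray      # corr > threshold (diagonal True)
    dissimilarity: np.ndarray  # cosine dissimilarity between adjacency rows
    silent_rois: np.ndarray    # ROIs with no quiet events (corr forced to 0)


def event_correlation(
    event_trains: list[EventTrain],
    quiet_mask: np.ndarray,
    corr_threshold: float = 0.7,
) -> CorrelationGraph:
    """Pairwise event correlation between ROIs during quiet wakefulness.

    Each ROI's events are reduced to a binary per-frame indicator restricted
    to the quiet samples.  ROIs without any quiet event have undefined
    correlation; they are assigned 0 against all others and flagged.
    """
    if len(event_trains) < 2:
        raise ValueError("need at least 2 ROIs")
    quiet_mask = np.asarray(quiet_mask, dtype=bool)
    if not quiet_mask.any():
        raise ValueError("quiet_mask selects no samples")
    ind = np.stack([tr.indicator()[quiet_mask] for tr in event_trains]).astype(float)
    n = ind.shape[0]
    sd = ind.std(axis=1)
    silent = sd == 0
    corr = np.zeros((n, n))
    active = np.flatnonzero(~silent)
    if len(active) >= 2:
        c = np.corrcoef(ind[active])
        corr[np.ix_(active, active)] = c
    np.fill_diagonal(corr, 1.0)
    adjacency = corr > corr_threshold
    np.fill_diagonal(adjacency, True)
    # cosine dissimilarity between adjacency rows; rows always have the
    # self-edge so norms never vanish
    rows = adjacency.astype(float)
    norms = np.linalg.norm(rows, axis=1)
    cos = (rows @ rows.T) / np.outer(norms, norms)
    dis = 1.0 - np.clip(cos, -1.0, 1.0)
    np.fill_diagonal(dis, 0.0)
    dis = 0.5 * (dis + dis.T)
    return CorrelationGraph(
        corr=corr,
        adjacency=adjacency,
        dissimilarity=dis,
        silent_rois=np.flatnonzero(silent),
    )


def cluster_fibers(
    graph: CorrelationGraph,
    cutoff: float = 0.75,
    method: str = "average",
) -> FiberMap:
    """Agglomerative clustering of the dissimilarity into fibers.

    Flat clusters are formed at cophenetic distance ``cutoff``.  Singleton
    clusters are allowed; every cluster is accepted (no manual screening
    step).  Labels are relabelled contiguously from 0 in order of first ROI
    appearance, so the result is invariant to ROI ordering up to labels.
    """
    dis = np.clip(np.asarray(graph.dissimilarity, dtype=float), 0.0, None)
    n = dis.shape[0]
    if n == 1:
        return FiberMap(assignments=np.zeros(1, dtype=int))
    Z = linkage(squareform(dis, checks=False), method=method)
    raw = fcluster(Z, t=cutoff, criterion="distance")
    # contiguous relabelling by first appearance
    labels = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        labels[i] = mapping.setdefault(int(r), len(mapping))
    return FiberMap(assignments=labels)


def fiber_trace(
    traces: list[StandardizedTrace] | None,
    member_rois: np.ndarray,
    session: RecordingSession | None = None,
) -> np.ndarray:
    """Mean standardized activity across a fiber's member ROIs."""
    member_rois = np.asarray(member_rois, dtype=int)
    if member_rois.size == 0:
        raise ValueError("fiber has no member ROIs")
    if traces is None:
        raise ValueError("standardized traces are required")
    if session is not None and member_rois.max() >= session.n_rois:
        raise IndexError("ROI id outside session")
    return np.mean([traces[i].z for i in member_rois], axis=0)
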