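"""From connectivity matrices to thresholded weighted graphs.

Group analysis proceeds: min-max normalise each subject's matrix over its 15
unique off-diagonal values, average the normalised matrices element-wise by
group, then cut the group matrix at the 70th percentile of its off-diagonal
values so that (with distinct values) exactly the 4 strongest of the 15
connections survive. The surviving connections form a weighted undirected
graph whose node set is always the full analysis ROI set - regions whose
connections fall below the cut remain as isolated nodes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import mean as _mean
from statistics import stdev as _stdev
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, DegenerateInputError, InputError
from .spectral import ConnectivityMatrix

__all__ = [
    "WeightedGraph",
    "EdgeSummary",
    "normalize_cm",
    "group_average",
    "percentile_threshold",
    "nearest_rank_threshold",
    "edge_summary",
]


@dataclass(frozen=True)
class WeightedGraph:
    """Thresholded undirected graph over the analysis ROIs.

    Edges are stored as ``(roi_a, roi_b, weight)`` with labels in sorted
    order within each pair and pairs sorted lexicographically, so the edge
    set is independent of the row order of the source matrix. Weights are
    the matrix entries themselves; nothing is re-scaled at graph
    construction.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    threshold_value: float
    percentile: float

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def has_edge(self, roi_a: str, roi_b: str) -> bool:
        a, b = sorted((roi_a, roi_b))
        return (a, b) in self.edge_pairs()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold_value=self.threshold_value, percentile=self.percentile)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


def normalize_cm(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Min-max normalise the unique off-diagonal values into [0, 1].

    The diagonal zeros are placeholders and are excluded from the min-max
    domain; they stay zero. A matrix whose off-diagonal values are all
    equal carries no ordering information and is rejected (the subject is
    dropped from group averaging upstream).
    """
    if cm.normalized:
        raise InputError("connectivity matrix is already normalized")
    vals = cm.offdiag_values()
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax == vmin:
        raise DegenerateInputError(
            "constant off-diagonal: min-max normalization undefined"
        )
    scaled = (cm.values - vmin) / (vmax - vmin)
    np.fill_diagonal(scaled, 0.0)
    scaled = (scaled + scaled.T) / 2.0  # exact symmetry under float arithmetic
    return cm.with_values(scaled, normalized=True)


def group_average(cms: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of normalised matrices from one group."""
    if not cms:
        raise InputError("cannot average an empty group")
    labels = cms[0].roi_labels
    for cm in cms:
        if not cm.normalized:
            raise InputError("group averaging requires normalized matrices")
        if cm.roi_labels != labels:
            raise InputError("ROI labels differ across matrices")
    values = np.mean([cm.values for cm in cms], axis=0)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return cms[0].with_values(values, normalized=True)


def nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(p*n/100), 1-based.

    For the 15 unique connections at p = 70 this is rank 11, so a strict
    cut above it retains exactly the 4 strongest when values are distinct
    (linear-interpolation percentiles would retain 5, contradicting the
    four-strongest rule the cut implements).
    """
    if not 0 < percentile <= 100:
        raise ConfigurationError("percentile must lie in (0, 100]")
    ordered = np.sort(np.asarray(values, float))
    rank = math.ceil(percentile * len(ordered) / 100.0)
    rank = min(max(rank, 1), len(ordered))
    return float(ordered[rank - 1])


def percentile_threshold(
    cm: ConnectivityMatrix, percentile: float = 70.0
) -> WeightedGraph:
    """Cut the matrix at the nearest-rank percentile of its unique values.

    Retention is strict (weight > threshold); values tied with the
    threshold are excluded and reported in a warning, keeping the edge set
    deterministic without an arbitrary tie order.
    """
    vals = cm.offdiag_values()
    pairs = cm.offdiag_pairs()
    threshold = nearest_rank_threshold(vals, percentile)
    edges = []
    tied = []
    for (a, b), v in zip(pairs, vals):
        lo, hi = sorted((a, b))
        if v > threshold:
            edges.append((lo, hi, float(v)))
        elif v == threshold:
            tied.append((lo, hi))
    # the nearest-rank value itself always sits at the threshold; only an
    # ambiguous tie (several pairs sharing that value) deserves a diagnostic
    if len(tied) > 1:
        warnings.warn(
            f"{len(tied)} pairs tied with the threshold {threshold:.6g} "
            f"and excluded: {tied}",
            stacklevel=2,
        )
    edges.sort(key=lambda e: (e[0], e[1]))
    return WeightedGraph(
        nodes=tuple(cm.roi_labels),
        edges=tuple(edges),
        threshold_value=threshold,
        percentile=float(percentile),
    )


@dataclass(frozen=True)
class EdgeSummary:
    """Retention summary of one connection across the subjects of a group.

    A subject is retained when the connection survives the percentile cut
    of that subject's own normalised matrix; mean and sd are computed over
    the retained subjects only (absent when no subject is retained).
    """

    edge: tuple[str, str]
    group: str
    retained_subjects: tuple[int, ...]
    n_group: int
    mean: float | None
    sd: float | None


def edge_summary(
    cms: Sequence[ConnectivityMatrix],
    subject_ids: Sequence[int],
    edge: tuple[str, str],
    percentile: float = 70.0,
    group: str = "",
) -> EdgeSummary:
    """Per-subject thresholding retention of one connection."""
    if len(cms) != len(subject_ids):
        raise InputError("one subject id per matrix required")
    for cm in cms:
        if not cm.normalized:
            raise InputError("edge summary requires normalized matrices")
    lo, hi = sorted(edge)
    if cms and (lo not in cms[0].roi_labels or hi not in cms[0].roi_labels):
        raise InputError(f"edge ({lo}, {hi}) not in ROI set")
    retained = []
    weights = []
    for sid, cm in zip(subject_ids, cms):
        graph = percentile_threshold(cm, percentile)
        if graph.has_edge(lo, hi):
            retained.append(sid)
            weights.append(cm.entry(lo, hi))
    mean = _mean(weights) if weights else None
    sd = _stdev(weights) if len(weights) >= 2 else None
    return EdgeSummary(
        edge=(lo, hi),
        group=group,
        retained_subjects=tuple(retained),
        n_group=len(cms),
        mean=mean,
        sd=sd,
    )
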