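"""Weighted nodal graph metrics on thresholded connectivity networks.

Degree centrality is the study's primary index: the sum of the weights of
all edges incident to a node, dc(i) = sum_j x_ij (j != i).  Nodal efficiency
and betweenness centrality are secondary metrics computed with the standard
weighted conventions (edge length = 1/weight; efficiency normalised by n-1;
betweenness unnormalised with fractional splitting of tied shortest paths).

Metric vectors are averaged across the sparsity sweep (unweighted arithmetic
mean over the 10 default thresholds) and left/right homologue ROIs are
collapsed into a single bilateral value by averaging.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .atlas import AtlasLabels
from .networks import ThresholdedNetwork

__all__ = [
    "METRICS",
    "degree_centrality",
    "nodal_efficiency",
    "betweenness_centrality",
    "compute_metric",
    "average_across_thresholds",
    "bilateral_average",
    "sweep_metrics",
    "bilateral_region_table",
    "metric_long_table",
]

METRICS = ("degree", "nodal_efficiency", "betweenness")


def degree_centrality(net: ThresholdedNetwork) -> np.ndarray:
    """Weighted degree: dc(i) = sum of edge weights incident to node i."""
    return net.weights.sum(axis=1)


def _length_graph(net: ThresholdedNetwork) -> csr_matrix:
    # shortest-path length of an edge is the inverse of its weight
    w = net.weights
    iu, ju = np.nonzero(np.triu(w, k=1))
    lengths = 1.0 / w[iu, ju]
    n = net.n
    g = csr_matrix((lengths, (iu, ju)), shape=(n, n))
    return g + g.T


def nodal_efficiency(net: ThresholdedNetwork) -> np.ndarray:
    """eff(i) = mean over j != i of 1/d(i, j); unreachable pairs add 0."""
    n = net.n
    if n < 2:
        return np.zeros(n)
    dist = dijkstra(_length_graph(net), directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0  # diagonal zeros and unreachable pairs
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness_centrality(net: ThresholdedNetwork) -> np.ndarray:
    """Weighted betweenness (Brandes), unnormalised, ties split fractionally.

    Each unordered pair {s, t} contributes the fraction of shortest s-t
    paths (by 1/weight edge length) passing through the node.
    """
    n = net.n
    g = nx.from_numpy_array(net.weights)
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(n)])


_METRIC_FUNCS = {
    "degree": degree_centrality,
    "nodal_efficiency": nodal_efficiency,
    "betweenness": betweenness_centrality,
}


def compute_metric(net: ThresholdedNetwork, metric: str) -> np.ndarray:
    try:
        func = _METRIC_FUNCS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}") from None
    return func(net)


def average_across_thresholds(vectors: Iterable[np.ndarray]) -> np.ndarray:
    """Unweighted arithmetic mean of per-node metric vectors over thresholds."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("need at least one threshold")
    lengths = {v.shape for v in vectors}
    if len(lengths) > 1:
        raise ValueError(f"mismatched vector lengths: {sorted(lengths)}")
    return np.mean(vectors, axis=0)


def bilateral_average(
    values: np.ndarray, atlas: AtlasLabels, region: str
) -> float:
    """Average a per-ROI vector over the left/right homologues of a region."""
    left, right = atlas.pair(region)
    values = np.asarray(values, dtype=float)
    return float((values[left] + values[right]) / 2.0)


def sweep_metrics(
    networks: Sequence[ThresholdedNetwork],
    metrics: Sequence[str] = ("degree",),
) -> dict[str, np.ndarray]:
    """Threshold-averaged per-node vectors for each requested metric."""
    return {
        m: average_across_thresholds([compute_metric(net, m) for net in networks])
        for m in metrics
    }


def bilateral_region_table(
    per_roi: pd.DataFrame, atlas: AtlasLabels, regions: Sequence[str]
) -> pd.DataFrame:
    """Collapse a (subjects x ROI) table to bilateral region columns.

    ``per_roi`` columns must be ROI names in atlas order-compatible naming;
    each output column is the mean of the region's _L and _R columns.
    """
    out = {}
    for region in regions:
        left, right = atlas.pair(region)
        out[region] = (
            per_roi[atlas.names[left]] + per_roi[atlas.names[right]]
        ) / 2.0
    return pd.DataFrame(out, index=per_roi.index)


def metric_long_table(
    per_subject: dict[str, dict[str, np.ndarray]],
    atlas: AtlasLabels,
) -> pd.DataFrame:
    """Long-format table (subject, metric, roi, value) from sweep results."""
    rows = []
    for sid, by_metric in per_subject.items():
        for metric, vec in by_metric.items():
            for name, val in zip(atlas.names, vec):
                rows.append((sid, metric, name, float(val)))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "roi", "value"])
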