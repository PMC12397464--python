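"""Subject-level functional-connectivity networks.

Cleaned ROI time series are turned into Pearson correlation matrices, Fisher
r-to-z transformed, and thresholded at a sweep of sparsity levels.  Networks
are weighted and undirected; only positive connections are eligible for
retention ("positive-weighted" networks), and retained weights are the
unmodified Fisher-z values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "DEFAULT_SPARSITIES",
    "correlation_matrix",
    "fisher_z",
    "threshold_by_sparsity",
    "sparsity_sweep",
]

logger = logging.getLogger(__name__)

#: The default sparsity sweep: 0.05 to 0.50 in steps of 0.05 (10 levels).
DEFAULT_SPARSITIES: tuple[float, ...] = tuple(
    np.round(np.arange(0.05, 0.501, 0.05), 2)
)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z connectivity matrix with zero diagonal."""

    subject_id: str
    z: np.ndarray
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if z.shape[0] != len(self.roi_names):
            raise ValueError("roi_names must match matrix size")
        if not np.isfinite(z).all():
            raise ValueError("non-finite entries in connectivity matrix")
        if np.abs(z - z.T).max() > 1e-12:
            raise ValueError("connectivity matrix not symmetric")
        if np.abs(np.diag(z)).max() > 0:
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Positive-weighted adjacency retaining the top-S fraction of edges."""

    sparsity: float
    weights: np.ndarray
    retained_edges: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def correlation_matrix(ts) -> np.ndarray:
    """Pearson correlation between all ROI pairs (symmetric, unit diagonal)."""
    data = np.asarray(ts.data if hasattr(ts, "data") else ts, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 volumes for a correlation matrix")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = getattr(ts, "roi_names", None)
        label = names[dead[0]] if names is not None else f"column {dead[0]}"
        raise ValueError(f"zero-variance ROI: {label}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(
    r: np.ndarray,
    subject_id: str = "",
    roi_names: tuple[str, ...] | None = None,
    clip: float = 0.999999,
) -> ConnectivityMatrix:
    """Fisher r-to-z transform (atanh) with clipping; diagonal set to zero."""
    r = np.asarray(r, dtype=float)
    if np.abs(r).max() > 1.0 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -clip, clip))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    if roi_names is None:
        roi_names = tuple(f"ROI{i:02d}" for i in range(r.shape[0]))
    return ConnectivityMatrix(subject_id=subject_id, z=z, roi_names=roi_names)


def _edge_count(n: int, sparsity: float) -> int:
    # round-half-away-from-zero on S * n(n-1)/2
    return int(np.floor(sparsity * n * (n - 1) / 2.0 + 0.5))


def threshold_by_sparsity(
    cm: ConnectivityMatrix, sparsity: float
) -> ThresholdedNetwork:
    """Keep the k = round(S * n(n-1)/2) strongest positive edges.

    Weights are preserved (weighted network, not binarised).  Ties at the
    cut are broken by ascending (i, j) index.  If fewer than k positive
    edges exist, all positive edges are kept and a warning is logged.
    """
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must lie in (0, 1]")
    n = cm.n
    k = _edge_count(n, sparsity)
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.z[iu, ju]
    pos = np.flatnonzero(vals > 0)
    if pos.size < k:
        logger.warning(
            "subject %s: only %d positive edges available for k=%d at S=%.3g",
            cm.subject_id, pos.size, k, sparsity,
        )
        keep = pos
    else:
        # stable sort on (-weight, i, j): lexsort with last key primary
        order = np.lexsort((ju[pos], iu[pos], -vals[pos]))
        keep = pos[order[:k]]
    w = np.zeros((n, n))
    w[iu[keep], ju[keep]] = vals[keep]
    w += w.T
    return ThresholdedNetwork(
        sparsity=float(sparsity), weights=w, retained_edges=int(keep.size)
    )


def sparsity_sweep(
    cm: ConnectivityMatrix,
    thresholds: tuple[float, ...] = DEFAULT_SPARSITIES,
) -> list[ThresholdedNetwork]:
    """Threshold at each sparsity level (default 0.05..0.50, 10 levels).

    Thresholds must be strictly increasing in (0, 1]; the resulting edge
    sets are nested (up to ties at the cut).
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds:
        raise ValueError("need at least one sparsity threshold")
    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return [threshold_by_sparsity(cm, t) for t in thresholds]
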