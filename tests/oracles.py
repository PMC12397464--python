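"""Independent reference implementations used to check the package.

These are deliberately naive (row sums, exhaustive path enumeration,
textbook formulas, pseudo-inverse projections) and share no code with the
implementations they verify.
"""

from __future__ import annotations

import itertools

import numpy as np


def row_sum_degree(weights: np.ndarray) -> np.ndarray:
    """Weighted degree by explicit per-node summation."""
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i] += weights[i, j]
    return out


def brute_shortest_paths(weights: np.ndarray, s: int, t: int):
    """All shortest simple paths s->t with length = sum of 1/weight.

    Returns (min_length, list_of_paths); (inf, []) when unreachable.
    Exponential - only for tiny graphs.
    """
    n = weights.shape[0]
    best = np.inf
    best_paths: list[tuple[int, ...]] = []
    nodes = [v for v in range(n) if v not in (s, t)]
    for k in range(len(nodes) + 1):
        for mid in itertools.permutations(nodes, k):
            path = (s, *mid, t)
            length = 0.0
            ok = True
            for a, b in zip(path, path[1:]):
                if weights[a, b] <= 0:
                    ok = False
                    break
                length += 1.0 / weights[a, b]
            if not ok:
                continue
            if length < best - 1e-12:
                best = length
                best_paths = [path]
            elif abs(length - best) <= 1e-12:
                best_paths.append(path)
    return best, best_paths


def brute_betweenness(weights: np.ndarray) -> np.ndarray:
    """Unnormalised weighted betweenness by exhaustive path enumeration."""
    n = weights.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            length, paths = brute_shortest_paths(weights, s, t)
            if not np.isfinite(length) or not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


def brute_nodal_efficiency(weights: np.ndarray) -> np.ndarray:
    """Nodal efficiency from exhaustively enumerated shortest paths."""
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i == j:
                continue
            length, _ = brute_shortest_paths(weights, i, j)
            if np.isfinite(length) and length > 0:
                acc += 1.0 / length
        out[i] = acc / (n - 1)
    return out


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, textbook step-up form."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


def first_order_partial_spearman(x, y, z) -> float:
    """r_xy.z from pairwise Spearman correlations (recursive formula)."""
    from scipy.stats import spearmanr

    r_xy = spearmanr(x, y).statistic
    r_xz = spearmanr(x, z).statistic
    r_yz = spearmanr(y, z).statistic
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def pinv_residuals(y: np.ndarray, confounders: np.ndarray) -> np.ndarray:
    """Least-squares residuals via the explicit pseudo-inverse."""
    n = y.shape[0]
    design = np.hstack([np.ones((n, 1)), confounders])
    return y - design @ (np.linalg.pinv(design) @ y)
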