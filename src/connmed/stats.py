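"""Covariate-adjusted rank-correlation inference for brain-behaviour links.

The central estimator is the partial Spearman correlation: every variable
(x, y and each covariate) is rank-transformed with average ranks for ties,
the x- and y-ranks are residualised on [intercept | covariate ranks], and
the coefficient is the Pearson correlation of the two residual vectors.
With no covariates this reduces exactly to the ordinary Spearman rho.
Two-sided p-values use the t approximation with n - 2 - #covariates degrees
of freedom.

Multiple comparisons across regions are handled by Benjamini-Hochberg FDR.
A seeded permutation test (shuffling the outcome only, keeping predictor
and covariate rows aligned) provides a nonparametric check: the empirical
p-value uses the add-one estimator (1 + #{|rho_b| >= |rho_obs|}) / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PartialCorrResult",
    "PermutationResult",
    "partial_spearman",
    "fdr_bh",
    "permutation_null",
    "roi_association_screen",
]


@dataclass(frozen=True)
class PartialCorrResult:
    x_name: str
    y_name: str
    covariate_names: tuple[str, ...]
    n: int
    rho: float
    p: float
    q: float | None = None


@dataclass(frozen=True)
class PermutationResult:
    observed_rho: float
    null_rhos: np.ndarray = field(repr=False)
    empirical_p: float
    B: int
    seed: int | None


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=0)


def _rank_residual_parts(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
):
    """Rank-transform, residualise on covariate ranks; return pieces.

    Returns (rx, ry, Q) where rx/ry are centred residual vectors of the x/y
    ranks and Q is an orthonormal basis of [intercept | covariate ranks]
    (used to project permuted outcomes cheaply).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("missing or non-finite values in x or y")
    if covariates is None or np.size(covariates) == 0:
        c = np.empty((n, 0))
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("covariate rows must match x length")
        if not np.isfinite(c).all():
            raise ValueError("missing or non-finite values in covariates")
    if n < c.shape[1] + 4:
        raise ValueError(f"n={n} too small for {c.shape[1]} covariates")
    xr, yr = _rank(x), _rank(y)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("degenerate variable: constant after ranking")
    design = np.hstack([np.ones((n, 1)), _rank(c) if c.shape[1] else c])
    q, _ = np.linalg.qr(design)
    rx = xr - q @ (q.T @ xr)
    ry = yr - q @ (q.T @ yr)
    return rx, ry, q


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates."""
    rx, ry, q = _rank_residual_parts(x, y, covariates)
    n = rx.shape[0]
    k = q.shape[1] - 1
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("degenerate variable: no residual variance")
    rho = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    with np.errstate(divide="ignore", over="ignore"):
        t = rho * np.sqrt(df / max(1.0 - rho**2, np.finfo(float).tiny))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df)))
    p = max(p, np.finfo(float).tiny)
    return PartialCorrResult(
        x_name=x_name,
        y_name=y_name,
        covariate_names=tuple(covariate_names),
        n=n,
        rho=rho,
        p=p,
    )


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_null(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    B: int = 5000,
    seed: int | None = None,
) -> PermutationResult:
    """Outcome-permutation null distribution for the partial Spearman rho.

    The outcome y is shuffled B times while x and the covariates keep their
    original alignment; the partial Spearman coefficient is recomputed for
    each shuffle.  Two-sided empirical p with the add-one estimator.
    """
    if B < 1:
        raise ValueError("B must be positive")
    if B < 100:
        warnings.warn(
            f"B={B} permutations give coarse p-value resolution", stacklevel=2
        )
    rx, ry, q = _rank_residual_parts(x, y, covariates)
    n = rx.shape[0]
    nx = np.linalg.norm(rx)
    ny = np.linalg.norm(ry)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate variable: no residual variance")
    rho_obs = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))

    rng = np.random.default_rng(seed)
    # Permuting y permutes its ranks; work directly on the rank vector.
    yranks = sps.rankdata(np.asarray(y, dtype=float).ravel())
    perm = np.argsort(rng.random((B, n)), axis=1)
    yp = yranks[perm].T  # n x B
    resid = yp - q @ (q.T @ yp)
    norms = np.linalg.norm(resid, axis=0)
    norms[norms == 0] = np.inf
    null_rhos = (rx @ resid) / (nx * norms)
    empirical_p = float((1 + np.sum(np.abs(null_rhos) >= abs(rho_obs))) / (B + 1))
    return PermutationResult(
        observed_rho=rho_obs,
        null_rhos=np.asarray(null_rhos),
        empirical_p=empirical_p,
        B=B,
        seed=seed,
    )


def roi_association_screen(
    values: pd.DataFrame,
    phenotypes: pd.DataFrame,
    regions: list[str] | tuple[str, ...],
    outcome: str,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    metric: str = "degree",
    permutation_B: int = 0,
    seed: int | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Partial Spearman screen of region metrics against one outcome.

    ``values`` is a (subjects x regions) table indexed by subject id (either
    bilateral region columns or the whole-atlas per-ROI table for the
    exploratory screen); ``phenotypes`` carries the outcome and covariates.
    q-values are computed across exactly the screened regions, in input
    order.  If ``permutation_B`` > 0 a seeded outcome-permutation p-value is
    added per region.
    """
    if not regions:
        raise ValueError("need at least one region")
    pheno = phenotypes.set_index("subject_id") if "subject_id" in phenotypes else phenotypes
    joined = values.join(pheno, how="inner")
    if len(joined) < min_n:
        raise ValueError(
            f"only {len(joined)} subjects after joining metrics and phenotypes"
        )
    cov = joined[list(covariates)].to_numpy(dtype=float) if covariates else None
    y = joined[outcome].to_numpy(dtype=float)
    rows = []
    rng = np.random.default_rng(seed)
    for region in regions:
        res = partial_spearman(
            joined[region].to_numpy(dtype=float),
            y,
            cov,
            x_name=f"{metric}:{region}",
            y_name=outcome,
            covariate_names=tuple(covariates),
        )
        row = {
            "region": region,
            "metric": metric,
            "outcome": outcome,
            "n": res.n,
            "rho": res.rho,
            "p": res.p,
        }
        if permutation_B > 0:
            child = int(rng.integers(0, 2**31 - 1))
            perm = permutation_null(
                joined[region].to_numpy(dtype=float), y, cov,
                B=permutation_B, seed=child,
            )
            row["empirical_p"] = perm.empirical_p
            row["B"] = permutation_B
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = fdr_bh(out["p"].to_numpy())
    return out
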