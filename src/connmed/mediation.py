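"""Simple (single-mediator) covariate-adjusted mediation with BC bootstrap.

The model is the classic X -> M -> Y path structure estimated by three
ordinary-least-squares regressions sharing one covariate set:

    M ~ X + covariates            (path a)
    Y ~ X + M + covariates        (paths b and c', the direct effect)
    Y ~ X + covariates            (path c, the total effect)

The indirect effect is a*b; with identical covariate sets the OLS identity
c = c' + a*b holds to numerical precision.  Inference on the indirect
effect uses case resampling (subjects with replacement) and a
bias-corrected (BC) percentile interval: z0 is the normal quantile of the
fraction of bootstrap estimates below the point estimate and the interval
endpoints sit at the Phi(2*z0 +/- z_{alpha/2}) percentiles of the bootstrap
distribution.  The indirect effect is declared significant when the CI
excludes zero.

By default x, m and y are z-scored before fitting, so paths are reported on
a standardised scale; set ``standardize=False`` for raw-unit coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MediationSpec",
    "bc_percentile_ci",
    "PathFit",
    "MediationResult",
    "fit_paths",
    "bootstrap_indirect",
    "run_mediation_suite",
]


@dataclass(frozen=True)
class MediationSpec:
    """Specification of one mediation model."""

    x_name: str
    m_name: str
    y_name: str
    covariate_names: tuple[str, ...] = ()
    n_boot: int = 5000
    alpha: float = 0.05
    standardize: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if len({self.x_name, self.m_name, self.y_name}) != 3:
            raise ValueError("x, m and y must be distinct variables")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PathFit:
    a: float
    b: float
    c: float
    c_prime: float
    se_a: float
    se_b: float
    se_c: float
    se_c_prime: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    n: int

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass(frozen=True)
class MediationResult:
    spec: MediationSpec
    paths: PathFit
    boot_indirects: np.ndarray = field(repr=False)
    ci_low: float
    ci_high: float
    n_degenerate: int

    @property
    def indirect(self) -> float:
        return self.paths.indirect

    @property
    def significant(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


def _ols(design: np.ndarray, y: np.ndarray):
    """OLS coefficients with classical standard errors and two-sided p."""
    n, p = design.shape
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise ValueError("rank-deficient design matrix (collinear columns)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - p
    sigma2 = resid @ resid / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    return beta, se, pvals


def _designs(data: pd.DataFrame, spec: MediationSpec):
    """Extract (x, m, y, covariate block) arrays, optionally z-scored."""
    cols = [spec.x_name, spec.m_name, spec.y_name, *spec.covariate_names]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    frame = data[cols].dropna()
    x = frame[spec.x_name].to_numpy(dtype=float)
    m = frame[spec.m_name].to_numpy(dtype=float)
    y = frame[spec.y_name].to_numpy(dtype=float)
    cov = frame[list(spec.covariate_names)].to_numpy(dtype=float)
    if spec.standardize:
        for v in (x, m, y):
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError("cannot standardise a constant variable")
            v -= v.mean()
            v /= sd
    return x, m, y, cov


def fit_paths(data: pd.DataFrame, spec: MediationSpec) -> PathFit:
    """Estimate paths a, b, c, c' by OLS with standard errors."""
    x, m, y, cov = _designs(data, spec)
    n = x.shape[0]
    ones = np.ones((n, 1))
    d_m = np.hstack([ones, x[:, None], cov])
    d_full = np.hstack([ones, x[:, None], m[:, None], cov])
    beta_m, se_m, p_m = _ols(d_m, m)
    beta_f, se_f, p_f = _ols(d_full, y)
    beta_t, se_t, p_t = _ols(d_m, y)
    return PathFit(
        a=float(beta_m[1]), b=float(beta_f[2]),
        c=float(beta_t[1]), c_prime=float(beta_f[1]),
        se_a=float(se_m[1]), se_b=float(se_f[2]),
        se_c=float(se_t[1]), se_c_prime=float(se_f[1]),
        p_a=float(p_m[1]), p_b=float(p_f[2]),
        p_c=float(p_t[1]), p_c_prime=float(p_f[1]),
        n=n,
    )


def _batched_coef(design_rows: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    """Solve least squares for each bootstrap batch via normal equations.

    design_rows: (B, n, p); y_rows: (B, n).  Returns (B, p) coefficients.
    """
    xtx = np.einsum("bni,bnj->bij", design_rows, design_rows)
    xty = np.einsum("bni,bn->bi", design_rows, y_rows)
    return np.linalg.solve(xtx, xty[..., None])[..., 0]


def bc_percentile_ci(
    boot: np.ndarray, point: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Bias-corrected percentile interval.

    z0 is the normal quantile of the fraction of bootstrap draws below the
    point estimate (clamped away from 0/1); the interval endpoints are the
    Phi(2*z0 +/- z_{alpha/2}) quantiles of the bootstrap distribution.
    When the bootstrap median sits at the point estimate (z0 = 0) this is
    the plain percentile interval.
    """
    boot = np.asarray(boot, dtype=float)
    B = boot.size
    frac = float(np.mean(boot < point))
    frac = min(max(frac, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = sps.norm.ppf(frac)
    z_alpha = sps.norm.ppf(alpha / 2.0)
    lo = sps.norm.cdf(2.0 * z0 + z_alpha)
    hi = sps.norm.cdf(2.0 * z0 - z_alpha)
    ci_low, ci_high = np.quantile(boot, [lo, hi])
    return float(ci_low), float(ci_high)


def bootstrap_indirect(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Bias-corrected bootstrap CI for the indirect effect a*b.

    Subjects are resampled with replacement ``n_boot`` times; the a and b
    paths are refit on each resample.  Rank-deficient resamples are redrawn
    (counted); more than 10% degenerate draws aborts.
    """
    x, m, y, cov = _designs(data, spec)
    n = x.shape[0]
    if n < 20:
        raise ValueError(f"n={n} too small for bootstrap mediation")
    paths = fit_paths(data, spec)
    point = paths.indirect
    B = spec.n_boot
    rng = np.random.default_rng(spec.seed)

    ones = np.ones((n, 1))
    d_m = np.hstack([ones, x[:, None], cov])
    d_full = np.hstack([ones, x[:, None], m[:, None], cov])

    ab = np.empty(B)
    filled = 0
    n_degenerate = 0
    max_degenerate = max(1, int(0.1 * B))
    while filled < B:
        todo = B - filled
        idx = rng.integers(0, n, size=(todo, n))
        gm = d_m[idx]            # (todo, n, p1)
        gf = d_full[idx]         # (todo, n, p2)
        # detect degenerate resamples (singular normal equations)
        xtx_m = np.einsum("bni,bnj->bij", gm, gm)
        xtx_f = np.einsum("bni,bnj->bij", gf, gf)
        ok = (np.linalg.matrix_rank(xtx_m) == gm.shape[2]) & (
            np.linalg.matrix_rank(xtx_f) == gf.shape[2]
        )
        bad = int((~ok).sum())
        if bad:
            n_degenerate += bad
            if n_degenerate > max_degenerate:
                raise ValueError(
                    f"{n_degenerate} degenerate bootstrap resamples (>10%); "
                    "increase the sample size"
                )
        good = np.flatnonzero(ok)
        if good.size:
            gi = idx[good]
            a_k = _batched_coef(d_m[gi], m[gi])[:, 1]
            b_k = _batched_coef(d_full[gi], y[gi])[:, 2]
            ab[filled : filled + good.size] = a_k * b_k
            filled += good.size

    ci_low, ci_high = bc_percentile_ci(ab, point, spec.alpha)
    return MediationResult(
        spec=spec,
        paths=paths,
        boot_indirects=ab,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_degenerate=n_degenerate,
    )


def run_mediation_suite(
    values: pd.DataFrame,
    phenotypes: pd.DataFrame,
    mediators: Sequence[str],
    x: str = "resilience",
    y: str = "speed",
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    n_boot: int = 5000,
    alpha: float = 0.05,
    standardize: bool = True,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[MediationResult]]:
    """Run one mediation model per configured mediator.

    Mediators are bilateral region names resolved in ``values`` (subjects x
    regions, indexed by subject id) or phenotype columns such as
    ``"education"``.  When education itself is the mediator it is removed
    from the covariate set (age and sex remain).  Returns a tidy summary
    table and the full result objects.
    """
    pheno = phenotypes.set_index("subject_id") if "subject_id" in phenotypes else phenotypes
    joined = values.join(pheno, how="inner") if values is not None else pheno
    rows = []
    results = []
    rng = np.random.default_rng(seed)
    for mediator in mediators:
        if mediator not in joined.columns:
            raise KeyError(f"mediator {mediator!r} not found")
        covs = tuple(c for c in covariates if c != mediator)
        spec = MediationSpec(
            x_name=x, m_name=mediator, y_name=y,
            covariate_names=covs, n_boot=n_boot, alpha=alpha,
            standardize=standardize, seed=int(rng.integers(0, 2**31 - 1)),
        )
        res = bootstrap_indirect(joined, spec)
        results.append(res)
        rows.append({
            "x": x, "m": mediator, "y": y,
            "covariates": ",".join(covs),
            "n": res.paths.n,
            "a": res.paths.a, "b": res.paths.b,
            "c": res.paths.c, "c_prime": res.paths.c_prime,
            "p_c_prime": res.paths.p_c_prime,
            "indirect": res.indirect,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "significant": res.significant,
            "n_boot": n_boot, "seed": spec.seed,
            "standardized": standardize,
        })
    return pd.DataFrame(rows), results
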