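"""Synthetic cohort generator with a planted brain-behaviour mediation.

Every downstream stage of the pipeline is exercised against cohorts whose
ground truth is known by construction.  The generative model:

* Psychological resilience ``X_i`` is drawn from a truncated normal matched
  to the target cohort marginals (mean 28.4, SD 5.63, bounded to the 0-45
  scale of the 15-item resilience questionnaire).
* A per-subject latent ``u_i = path_a * z(X_i) + noise`` couples resilience
  to the brain: the off-diagonal covariance entries touching the target
  region's ROIs are scaled by ``(1 + gain * u_i)``, so higher resilience
  lowers the target region's population degree centrality when
  ``path_a < 0``.  Modulating the covariance directly (rather than adding
  signal) keeps the planted effect analytically checkable on the exact
  matrix.
* Processing speed ``Y_i = path_b * u_i + path_c_prime * z(X_i) +
  covariate effects + noise``, mapped affinely to the SDMT scale
  (mean 53.9, SD 10.7) and rounded to a non-negative integer.  With
  ``path_a < 0`` and ``path_b < 0`` the measured degree centrality
  correlates negatively with both behaviours and the indirect effect
  a*b on speed is positive - the qualitative pattern the pipeline is
  designed to detect.
* ROI time series are stationary AR(1) processes whose innovation
  covariance is the modulated matrix; a shared low-frequency "global"
  signal and smooth tissue confounds plus random-walk head motion (with
  occasional step-like spikes) give the cleaning stage real work to do.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from .atlas import AtlasLabels, default_atlas
from .cleaning import ConfoundSet, SubjectTimeSeries

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "make_covariance",
    "simulate_timeseries",
    "generate_phenotypes",
    "generate_motion",
    "generate_cohort",
    "write_cohort",
]

#: Cohort marginals the generator targets (matching the emulated study).
RESILIENCE_MEAN, RESILIENCE_SD = 28.4, 5.63
SPEED_MEAN, SPEED_SD = 53.9, 10.7
EDUCATION_MEAN, EDUCATION_SD = 12.2, 4.67
AGE_RANGE = (60.0, 79.0)
P_MALE = 28 / 101


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters (and, after generation, realised latents).

    ``path_a`` couples the latent to standardised resilience; ``path_b``
    couples speed to the latent; ``path_c_prime`` is the direct
    resilience -> speed path.  ``modulation_gain`` converts the latent into
    the covariance scaling factor (1 + gain * u).

    The defaults plant a full mediation as it would be OBSERVED: because
    the measured degree centrality is a noisy proxy of the latent (finite
    scan length bounds its reliability near 0.9), classical
    errors-in-variables attenuation transfers a small positive share of
    the latent-mediated association into the fitted direct path; the small
    negative default ``path_c_prime`` offsets that known bias so the
    fitted direct effect is centred on zero, matching a cohort whose
    association is fully mediated by the target region's connectivity.
    """

    path_a: float = -0.55
    path_b: float = -0.55
    path_c_prime: float = -0.11
    covariate_effects: dict = field(
        default_factory=lambda: {"age": -0.5, "sex": 0.0, "education": 0.3}
    )
    noise_sds: dict = field(
        default_factory=lambda: {"latent": 0.8, "speed": 0.75}
    )
    target_region: str = "Thalamus"
    base_correlation: float = 0.3
    loading_range: tuple[float, float] | None = (0.45, 0.75)
    modulation_gain: float = 0.4
    ar_coefficient: float = 0.2
    global_coupling: float = 0.2
    seed: int = 0
    subject_latent: np.ndarray | None = field(default=None, repr=False)
    modulations: np.ndarray | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("subject_latent", "modulations"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return d


@dataclass(frozen=True)
class SyntheticCohort:
    timeseries: list[SubjectTimeSeries]
    confounds: list[ConfoundSet]
    phenotypes: pd.DataFrame
    truth: GroundTruth
    atlas: AtlasLabels

    def __post_init__(self) -> None:
        ids_ts = [t.subject_id for t in self.timeseries]
        ids_cf = [c.subject_id for c in self.confounds]
        ids_ph = list(self.phenotypes["subject_id"])
        if not (ids_ts == ids_cf == ids_ph):
            raise ValueError("subject ids/order differ across cohort components")

    @property
    def subject_ids(self) -> list[str]:
        return [t.subject_id for t in self.timeseries]


def make_covariance(
    n_rois: int,
    base_correlation: float,
    target_roi: int | tuple[int, ...],
    modulation: float,
    loadings: np.ndarray | None = None,
    min_eigenvalue: float = 1e-8,
) -> np.ndarray:
    """Correlation matrix with a modulated target row/column.

    The base is exchangeable (every off-diagonal entry equals
    ``base_correlation``) unless per-ROI factor ``loadings`` are supplied,
    in which case the base entry for pair (i, j) is ``l_i * l_j`` - a
    single-factor structure that gives the broad edge-strength distribution
    typical of empirical connectivity matrices.  Off-diagonal entries
    touching any target ROI are then scaled by ``(1 + modulation)``
    (entries between two targets are scaled once) and clipped into
    (-0.99, 0.99).  If the result is not positive definite it is shrunk
    toward the identity until the smallest eigenvalue exceeds
    ``min_eigenvalue``; irreparable matrices raise.
    """
    if n_rois < 3:
        raise ValueError("n_rois must be >= 3")
    targets = np.atleast_1d(np.asarray(target_roi, dtype=int))
    if (targets < 0).any() or (targets >= n_rois).any():
        raise ValueError("target_roi out of range")
    if loadings is None:
        cov = np.full((n_rois, n_rois), float(base_correlation))
    else:
        loadings = np.asarray(loadings, dtype=float)
        if loadings.shape != (n_rois,):
            raise ValueError("loadings must have one entry per ROI")
        cov = np.outer(loadings, loadings)
    np.fill_diagonal(cov, 1.0)
    mask = np.zeros(n_rois, dtype=bool)
    mask[targets] = True
    touch = mask[:, None] | mask[None, :]
    np.fill_diagonal(touch, False)
    cov[touch] *= 1.0 + modulation
    off = ~np.eye(n_rois, dtype=bool)
    cov[off] = np.clip(cov[off], -0.99, 0.99)
    cov = (cov + cov.T) / 2.0
    for lam in np.arange(0.0, 1.0, 0.05):
        cand = (1.0 - lam) * cov + lam * np.eye(n_rois)
        if np.linalg.eigvalsh(cand)[0] > min_eigenvalue:
            return cand
    raise ValueError(
        f"covariance not repairable to positive definite "
        f"(base={base_correlation}, modulation={modulation})"
    )


def simulate_timeseries(
    cov: np.ndarray,
    n_volumes: int,
    ar_coefficient: float,
    seed: int,
    tr_seconds: float = 2.0,
    subject_id: str = "sim",
    roi_names: tuple[str, ...] | None = None,
    burn_in: int = 100,
) -> SubjectTimeSeries:
    """Stationary AR(1) series with innovation covariance ``cov``.

    ``x_t = phi * x_{t-1} + e_t`` with ``e_t ~ N(0, cov)``; the lag-1
    autocorrelation of every ROI equals ``phi`` and the stationary
    correlation structure equals that of ``cov``.  Fixed seed gives
    bit-identical output.
    """
    cov = np.asarray(cov, dtype=float)
    n_rois = cov.shape[0]
    if not (0.0 <= ar_coefficient < 1.0):
        raise ValueError("ar_coefficient must lie in [0, 1)")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance must be positive definite") from err
    if n_volumes < 10 * n_rois:
        warnings.warn(
            "n_volumes < 10 x n_rois: correlation estimates may be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    burn = 0 if ar_coefficient == 0.0 else burn_in
    innov = rng.standard_normal((n_volumes + burn, n_rois)) @ chol.T
    if ar_coefficient == 0.0:
        data = innov
    else:
        data = signal.lfilter([1.0], [1.0, -ar_coefficient], innov, axis=0)
        data = data[burn:]
    if roi_names is None:
        roi_names = tuple(f"ROI{i:02d}" for i in range(n_rois))
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=np.ascontiguousarray(data),
        tr_seconds=tr_seconds,
        roi_names=roi_names,
    )


def _truncnorm(rng, mean, sd, lower, upper, size):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_phenotypes(
    truth: GroundTruth, n_subjects: int, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Draw phenotypes and the latent chain; returns (table, extras).

    extras carries the realised latents ``u``, the covariance modulations,
    and the un-rounded speed values (useful for exact checks).
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    rng = np.random.default_rng(seed)
    resilience = np.round(
        _truncnorm(rng, RESILIENCE_MEAN, RESILIENCE_SD, 0, 45, n_subjects)
    )
    zx = _zscore(resilience)
    u = truth.path_a * zx + truth.noise_sds["latent"] * rng.standard_normal(n_subjects)
    # smooth squash keeps per-subject correlations inside (-1, 1) without the
    # kink a hard clip would put in the connectivity-latent response
    modulation = 0.9 * np.tanh(truth.modulation_gain * u / 0.9)

    age = rng.uniform(*AGE_RANGE, size=n_subjects)
    sex = (rng.random(n_subjects) < P_MALE).astype(int)  # 1 = male
    education = np.round(
        _truncnorm(rng, EDUCATION_MEAN, EDUCATION_SD, 0, np.inf, n_subjects)
    )
    moca = np.round(_truncnorm(rng, 26.0, 2.0, 22, 30, n_subjects))
    gds = np.round(_truncnorm(rng, 2.0, 1.8, 0, 7, n_subjects))

    eff = truth.covariate_effects
    speed_std = (
        truth.path_b * u
        + truth.path_c_prime * zx
        + eff.get("age", 0.0) * _zscore(age)
        + eff.get("sex", 0.0) * (sex - sex.mean())
        + eff.get("education", 0.0) * _zscore(education)
        + truth.noise_sds["speed"] * rng.standard_normal(n_subjects)
    )
    sd = speed_std.std(ddof=0)
    speed_raw = SPEED_MEAN + (SPEED_SD * speed_std / sd if sd > 0 else 0.0)
    speed = np.maximum(np.round(speed_raw), 0.0)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)],
            "age": np.round(age, 1),
            "sex": sex,
            "education": education,
            "resilience": resilience.astype(int),
            "speed": speed.astype(int),
            "moca": moca.astype(int),
            "gds": gds.astype(int),
        }
    )
    extras = {"latent": u, "modulation": modulation, "speed_raw": speed_raw,
              "z_resilience": zx}
    return table, extras


def generate_motion(
    n_volumes: int,
    spike_probability: float,
    seed: int,
    step_sd_mm: float = 0.02,
    step_sd_rad: float = 2e-4,
    spike_magnitude_mm: tuple[float, float] = (0.6, 1.0),
    subject_id: str = "sim",
) -> ConfoundSet:
    """Random-walk rigid-body motion with step-like spikes, plus tissue signals.

    Motion is a Gaussian random walk in 3 translations (mm) and 3 rotations
    (radians).  With probability ``spike_probability`` a volume receives a
    persistent translation offset of 0.6-1.0 mm (random axis and sign) -
    a head repositioning - producing exactly one framewise-displacement
    exceedance per spike.  Tissue/global signals are smooth low-frequency
    sinusoid mixtures.
    """
    if not (0.0 <= spike_probability <= 1.0):
        raise ValueError("spike_probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_volumes, 6))
    steps[1:, :3] = rng.normal(0.0, step_sd_mm, size=(n_volumes - 1, 3))
    steps[1:, 3:] = rng.normal(0.0, step_sd_rad, size=(n_volumes - 1, 3))
    spikes = rng.random(n_volumes) < spike_probability
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        mag = rng.uniform(*spike_magnitude_mm) * rng.choice([-1.0, 1.0])
        steps[t, axis] += mag
    motion = np.cumsum(steps, axis=0)

    t_axis = np.arange(n_volumes)
    tissue = np.empty((n_volumes, 3))
    for j in range(3):
        freqs = rng.uniform(0.005, 0.04, size=2)
        phases = rng.uniform(0.0, 2 * np.pi, size=2)
        amps = rng.uniform(0.5, 1.0, size=2)
        # TR-spaced samples of slow oscillations (TR assumed 2 s here only
        # to set the frequency scale; the signals are nuisance regressors)
        tissue[:, j] = sum(
            a * np.sin(2 * np.pi * f * 2.0 * t_axis + ph)
            for a, f, ph in zip(amps, freqs, phases)
        )
    return ConfoundSet(subject_id=subject_id, motion6=motion, tissue_signals=tissue)


def generate_cohort(
    n_subjects: int = 101,
    n_rois: int = 90,
    n_volumes: int = 240,
    tr_seconds: float = 2.0,
    truth: GroundTruth | None = None,
    spike_probability: float = 0.005,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a full cohort (time series, confounds, phenotypes, truth).

    The planted effect modulates the covariance rows of both hemispheres of
    ``truth.target_region``.  A shared low-frequency global signal is mixed
    into every ROI (strength ``truth.global_coupling``) so that nuisance
    regression has a real target.
    """
    if truth is None:
        truth = GroundTruth(seed=0 if seed is None else int(seed))
    master = np.random.SeedSequence(truth.seed if seed is None else int(seed))
    s_pheno, s_ts, s_motion, s_base = master.spawn(4)
    atlas = default_atlas(n_rois)
    loadings = None
    if truth.loading_range is not None:
        loadings = np.random.default_rng(s_base).uniform(
            *truth.loading_range, size=n_rois
        )
    phenotypes, extras = generate_phenotypes(
        truth, n_subjects, seed=s_pheno
    )
    targets = atlas.indices(truth.target_region)
    ts_seeds = s_ts.spawn(n_subjects)
    mo_seeds = s_motion.spawn(n_subjects)
    timeseries: list[SubjectTimeSeries] = []
    confounds: list[ConfoundSet] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-scan warning is expected here
        for i, sid in enumerate(phenotypes["subject_id"]):
            cov = make_covariance(
                n_rois, truth.base_correlation, targets,
                float(extras["modulation"][i]), loadings=loadings,
            )
            ts = simulate_timeseries(
                cov, n_volumes, truth.ar_coefficient, seed=ts_seeds[i],
                tr_seconds=tr_seconds, subject_id=sid, roi_names=atlas.names,
            )
            conf = generate_motion(
                n_volumes, spike_probability, seed=mo_seeds[i], subject_id=sid
            )
            if truth.global_coupling:
                contaminated = ts.data + (
                    truth.global_coupling * conf.tissue_signals[:, 2][:, None]
                )
                ts = dataclasses.replace(ts, data=contaminated)
            timeseries.append(ts)
            confounds.append(conf)
    truth = dataclasses.replace(
        truth,
        subject_latent=np.asarray(extras["latent"]),
        modulations=np.asarray(extras["modulation"]),
    )
    return SyntheticCohort(
        timeseries=timeseries,
        confounds=confounds,
        phenotypes=phenotypes,
        truth=truth,
        atlas=atlas,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort in the pipeline's on-disk layout.

    timeseries/<id>.tsv (header = ROI names), motion/<id>.txt (6 columns,
    whitespace), tissue/<id>.tsv, phenotypes.tsv, atlas.tsv and a
    truth.json sidecar with the planted parameters and seed.
    """
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(exist_ok=True)
    (outdir / "tissue").mkdir(exist_ok=True)
    for ts, conf in zip(cohort.timeseries, cohort.confounds):
        pd.DataFrame(ts.data, columns=list(ts.roi_names)).to_csv(
            outdir / "timeseries" / f"{ts.subject_id}.tsv", sep="\t", index=False
        )
        np.savetxt(outdir / "motion" / f"{conf.subject_id}.txt", conf.motion6)
        pd.DataFrame(
            conf.tissue_signals, columns=["white_matter", "csf", "global"]
        ).to_csv(outdir / "tissue" / f"{conf.subject_id}.tsv", sep="\t", index=False)
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    cohort.atlas.to_frame().to_csv(outdir / "atlas.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_json_dict(), fh, indent=2)
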