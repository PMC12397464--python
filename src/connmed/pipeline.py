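"""Configuration-driven orchestration of the full analysis chain.

``run_study`` executes: cohort QC -> per-subject cleaning -> connectivity
networks -> threshold-averaged nodal metrics -> covariate-adjusted
association screen (optionally permutation-validated) -> bootstrap
mediation suite, either on files on disk or on an in-memory synthetic
cohort, and records a manifest (config hash, seeds, per-stage counts)
sufficient to reproduce the run.  One master seed fans out to
stage-specific child seeds through a stable derivation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .atlas import TARGET_REGIONS
from .cleaning import clean_subject, motion_summary, qc_filter
from .metrics import bilateral_region_table, sweep_metrics
from .networks import DEFAULT_SPARSITIES, correlation_matrix, fisher_z, sparsity_sweep
from .stats import roi_association_screen
from .mediation import run_mediation_suite
from .synthetic import GroundTruth, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "StudyResult", "run_study", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a study run, pre-filled with the reference defaults."""

    # input locations (file mode); ignored when synthetic_n_subjects is set
    timeseries_dir: str | None = None
    motion_dir: str | None = None
    tissue_dir: str | None = None
    phenotype_file: str | None = None
    atlas_file: str | None = None
    # synthetic mode
    synthetic: bool = False
    n_subjects: int = 101
    n_rois: int = 90
    n_volumes: int = 240
    truth: GroundTruth | None = None
    spike_probability: float = 0.005
    # preprocessing
    tr_seconds: float = 2.0
    n_discard: int = 5
    fd_threshold_mm: float = 0.5
    low_hz: float = 0.01
    high_hz: float = 0.1
    rotation_unit: str = "radians"
    motion_rule: str = "conjunction"
    moca_min: float = 22
    gds_max: float = 7
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    max_mean_fd_mm: float = 0.2
    # networks and metrics
    sparsities: tuple[float, ...] = DEFAULT_SPARSITIES
    metrics: tuple[str, ...] = ("degree",)
    target_regions: tuple[str, ...] = TARGET_REGIONS
    # statistics
    outcomes: tuple[str, ...] = ("speed", "resilience")
    covariates: tuple[str, ...] = ("age", "sex", "education")
    permutation_B: int = 5000
    run_permutation: bool = False
    n_boot: int = 5000
    mediation_x: str = "resilience"
    mediation_y: str = "speed"
    include_education_mediator: bool = True
    standardize_mediation: bool = True
    # run control
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        truth = raw.pop("truth", None)
        cfg = cls(**raw)
        if truth is not None:
            cfg.truth = GroundTruth(**truth)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.truth is not None:
            d["truth"] = self.truth.to_json_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class StudyResult:
    qc: pd.DataFrame
    metrics_by_name: dict[str, pd.DataFrame]       # metric -> subjects x ROI
    region_values: dict[str, pd.DataFrame]          # metric -> subjects x region
    associations: pd.DataFrame | None
    mediation: pd.DataFrame | None
    manifest: dict
    cohort: SyntheticCohort | None = None


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    """Return (timeseries list, confounds list, phenotypes, atlas)."""
    if config.synthetic:
        truth = config.truth if config.truth is not None else GroundTruth(seed=config.seed)
        cohort = generate_cohort(
            n_subjects=config.n_subjects,
            n_rois=config.n_rois,
            n_volumes=config.n_volumes,
            tr_seconds=config.tr_seconds,
            truth=truth,
            spike_probability=config.spike_probability,
            seed=config.seed,
        )
        return cohort.timeseries, cohort.confounds, cohort.phenotypes, cohort.atlas, cohort
    for name in ("timeseries_dir", "motion_dir", "phenotype_file", "atlas_file"):
        if getattr(config, name) is None:
            raise ValueError(f"config.{name} required for a file-based run")
    atlas = cio.read_atlas(config.atlas_file)
    phenotypes = cio.read_phenotypes(config.phenotype_file)
    subjects = cio.list_subjects(config.timeseries_dir)
    timeseries, confounds = [], []
    for sid in subjects:
        ts = cio.read_timeseries(
            Path(config.timeseries_dir) / f"{sid}.tsv", config.tr_seconds, sid
        )
        tissue = (
            Path(config.tissue_dir) / f"{sid}.tsv" if config.tissue_dir else None
        )
        conf = cio.read_motion(
            Path(config.motion_dir) / f"{sid}.txt", tissue, sid,
            rotation_unit=config.rotation_unit,
        )
        timeseries.append(ts)
        confounds.append(conf)
    phenotypes = phenotypes[phenotypes["subject_id"].isin(subjects)].reset_index(drop=True)
    return timeseries, confounds, phenotypes, atlas, None


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full chain; see module docstring for stage order."""
    t0 = time.time()
    master = np.random.SeedSequence(config.seed)
    _, s_perm, s_boot = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(3))
    timeseries, confounds, phenotypes, atlas, cohort = _load_inputs(config)
    manifest: dict = {
        "package": "connmed",
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {"permutation": s_perm, "mediation": s_boot},
        "stages": {},
    }

    # --- QC -------------------------------------------------------------
    pheno_idx = phenotypes.set_index("subject_id")
    qc_rows = []
    for conf in confounds:
        row = {"subject_id": conf.subject_id}
        row.update(motion_summary(conf))
        for f in ("moca", "gds"):
            row[f] = (
                pheno_idx.loc[conf.subject_id, f]
                if conf.subject_id in pheno_idx.index and f in pheno_idx.columns
                else np.nan
            )
        qc_rows.append(row)
    included, reports = qc_filter(
        pd.DataFrame(qc_rows),
        moca_min=config.moca_min,
        gds_max=config.gds_max,
        max_translation_mm=config.max_translation_mm,
        max_rotation_deg=config.max_rotation_deg,
        max_mean_fd_mm=config.max_mean_fd_mm,
        motion_rule=config.motion_rule,
    )
    qc_table = pd.DataFrame(
        [
            {**dataclasses.asdict(r), "reasons": ";".join(r.reasons)}
            for r in reports
        ]
    )
    manifest["stages"]["qc"] = {
        "n_input": len(confounds), "n_included": len(included),
    }
    logger.info("qc: %d/%d subjects included", len(included), len(confounds))

    keep = set(included)
    timeseries = [t for t in timeseries if t.subject_id in keep]
    confounds = [c for c in confounds if c.subject_id in keep]

    # --- cleaning, networks, metrics ------------------------------------
    per_subject: dict[str, dict[str, np.ndarray]] = {}
    for ts, conf in zip(timeseries, confounds):
        try:
            cleaned, _info = clean_subject(
                ts, conf,
                n_discard=config.n_discard,
                fd_threshold_mm=config.fd_threshold_mm,
                low_hz=config.low_hz,
                high_hz=config.high_hz,
            )
            cm = fisher_z(
                correlation_matrix(cleaned), ts.subject_id, ts.roi_names
            )
            nets = sparsity_sweep(cm, config.sparsities)
            per_subject[ts.subject_id] = sweep_metrics(nets, config.metrics)
        except Exception as err:
            raise RuntimeError(
                f"stage cleaning/networks failed for subject {ts.subject_id}: {err}"
            ) from err
    manifest["stages"]["networks"] = {
        "n_subjects": len(per_subject),
        "sparsities": list(config.sparsities),
    }

    metrics_by_name = {
        m: pd.DataFrame(
            {sid: vals[m] for sid, vals in per_subject.items()},
            index=list(atlas.names),
        ).T
        for m in config.metrics
    }
    region_values = {
        m: bilateral_region_table(df, atlas, config.target_regions)
        for m, df in metrics_by_name.items()
    }

    # --- associations and mediation -------------------------------------
    associations = None
    mediation_table = None
    if config.target_regions:
        assoc_frames = []
        for m in config.metrics:
            for outcome in config.outcomes:
                assoc_frames.append(
                    roi_association_screen(
                        region_values[m],
                        phenotypes,
                        list(config.target_regions),
                        outcome=outcome,
                        covariates=config.covariates,
                        metric=m,
                        permutation_B=(
                            config.permutation_B if config.run_permutation else 0
                        ),
                        seed=s_perm,
                    )
                )
        associations = pd.concat(assoc_frames, ignore_index=True)
        mediators = list(config.target_regions)
        if config.include_education_mediator and "education" in config.covariates:
            mediators.append("education")
        primary_metric = config.metrics[0]
        mediation_table, _ = run_mediation_suite(
            region_values[primary_metric],
            phenotypes,
            mediators,
            x=config.mediation_x,
            y=config.mediation_y,
            covariates=config.covariates,
            n_boot=config.n_boot,
            standardize=config.standardize_mediation,
            seed=s_boot,
        )
        manifest["stages"]["associations"] = {"n_tests": len(associations)}
        manifest["stages"]["mediation"] = {"n_models": len(mediation_table)}
    else:
        manifest["stages"]["associations"] = "skipped (empty region list)"
        manifest["stages"]["mediation"] = "skipped (empty region list)"

    manifest["elapsed_seconds"] = round(time.time() - t0, 3)

    result = StudyResult(
        qc=qc_table,
        metrics_by_name=metrics_by_name,
        region_values=region_values,
        associations=associations,
        mediation=mediation_table,
        manifest=manifest,
        cohort=cohort,
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: StudyResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc.to_csv(out / "qc.tsv", sep="\t", index=False)
    for m, df in result.metrics_by_name.items():
        df.rename_axis("subject_id").to_csv(out / f"metrics_{m}.tsv", sep="\t")
    for m, df in result.region_values.items():
        df.rename_axis("subject_id").to_csv(out / f"regions_{m}.tsv", sep="\t")
    if result.associations is not None:
        result.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    if result.mediation is not None:
        result.mediation.to_csv(out / "mediation.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def validate_inputs(
    timeseries_dir: str | Path,
    motion_dir: str | Path,
    phenotype_file: str | Path,
    atlas_file: str | Path,
    tr_seconds: float = 2.0,
    expected_volumes: int | None = None,
) -> pd.DataFrame:
    """Report-only consistency check of a file-based input layout.

    Flags column-count mismatches against the atlas, volume-count
    anomalies, subjects missing from any source, and unreadable files.
    Returns a table (subject_id, issue); empty when fully consistent.
    """
    issues: list[tuple[str, str]] = []
    atlas = cio.read_atlas(atlas_file)
    phenotypes = cio.read_phenotypes(phenotype_file)
    ts_subjects = set(cio.list_subjects(timeseries_dir))
    ph_subjects = set(phenotypes["subject_id"])
    for sid in sorted(ph_subjects - ts_subjects):
        issues.append((sid, "phenotype row without time-series file"))
    for sid in sorted(ts_subjects - ph_subjects):
        issues.append((sid, "time-series file without phenotype row"))
    for sid in sorted(ts_subjects):
        try:
            ts = cio.read_timeseries(
                Path(timeseries_dir) / f"{sid}.tsv", tr_seconds, sid
            )
        except Exception as err:
            issues.append((sid, f"unreadable time series: {err}"))
            continue
        if ts.n_rois != atlas.n_rois:
            issues.append(
                (sid, f"{ts.n_rois} ROI columns but atlas has {atlas.n_rois}")
            )
        if expected_volumes is not None and ts.n_volumes != expected_volumes:
            issues.append(
                (sid, f"{ts.n_volumes} volumes, expected {expected_volumes}")
            )
        motion_path = Path(motion_dir) / f"{sid}.txt"
        if not motion_path.exists():
            issues.append((sid, "missing motion file"))
        else:
            try:
                conf = cio.read_motion(motion_path, None, sid)
                if conf.motion6.shape[0] != ts.n_volumes:
                    issues.append(
                        (sid, "motion rows do not match time-series volumes")
                    )
            except Exception as err:
                issues.append((sid, f"unreadable motion file: {err}"))
    missing_pheno = [
        c for c in ("age", "sex", "education", "resilience", "speed")
        if c not in phenotypes.columns
    ]
    if missing_pheno:
        issues.append(("<cohort>", f"phenotype columns missing: {missing_pheno}"))
    return pd.DataFrame(issues, columns=["subject_id", "issue"])
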