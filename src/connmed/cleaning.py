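"""Temporal preprocessing of ROI time series and cohort-level motion QC.

The cleaning chain applied to each subject is fixed and logged:

1. discard initial volumes (scanner equilibration),
2. framewise displacement (FD) from the six rigid-body parameters,
3. spike (scrubbing) regressors for high-motion volumes,
4. joint nuisance regression: tissue/global signals + Friston-24 motion
   expansion + spike regressors,
5. zero-phase band-pass filtering (default 0.01-0.1 Hz).

FD follows the Power convention: the L1 norm of the six back-differences,
with rotations (radians) converted to arc length on a 50 mm sphere.  Volumes
with FD above a threshold are censored by adding one unit-impulse column per
flagged volume (the flagged volume, one before, two after) to the nuisance
design, rather than by deleting rows.

Cohort-level QC excludes subjects on cognitive screening (MoCA), depression
screening (GDS) and head motion (maximum absolute translation/rotation and
mean FD).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SubjectTimeSeries",
    "ConfoundSet",
    "QCReport",
    "discard_initial",
    "framewise_displacement",
    "build_scrub_regressors",
    "expand_friston24",
    "regress_confounds",
    "bandpass",
    "qc_filter",
    "motion_summary",
    "clean_subject",
]


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's ROI time series (volumes x ROIs) with TR metadata."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("time-series data must be 2-D (volumes x ROIs)")
        if data.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        if data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"{data.shape[1]} columns but {len(self.roi_names)} ROI names"
            )
        if not np.isfinite(data).all():
            raise ValueError(f"non-finite values in time series {self.subject_id}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ConfoundSet:
    """Per-subject nuisance signals aligned with the time series.

    ``motion6`` holds 3 translations (mm) and 3 rotations (radians), one row
    per volume.  ``tissue_signals`` holds white-matter, CSF and global mean
    signals (columns in that order); it may be ``None`` when unavailable.
    """

    subject_id: str
    motion6: np.ndarray
    tissue_signals: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.motion6, dtype=float))
        object.__setattr__(self, "motion6", m)
        if m.shape[1] != 6:
            raise ValueError("motion6 must have 6 columns")
        if self.tissue_signals is not None:
            t = np.atleast_2d(np.asarray(self.tissue_signals, dtype=float))
            if t.shape[0] != m.shape[0]:
                raise ValueError("tissue_signals rows must match motion6 rows")
            object.__setattr__(self, "tissue_signals", t)

    def drop_initial(self, n_discard: int) -> "ConfoundSet":
        """Remove the first ``n_discard`` rows (companion to discard_initial)."""
        if n_discard >= self.motion6.shape[0]:
            raise ValueError("cannot discard all confound rows")
        tissue = (
            None if self.tissue_signals is None else self.tissue_signals[n_discard:]
        )
        return ConfoundSet(self.subject_id, self.motion6[n_discard:], tissue)


@dataclass(frozen=True)
class QCReport:
    subject_id: str
    max_abs_translation_mm: float
    max_abs_rotation_deg: float
    mean_fd_mm: float
    moca: float
    gds: float
    included: bool
    reasons: tuple[str, ...]


def discard_initial(ts: SubjectTimeSeries, n_discard: int = 5) -> SubjectTimeSeries:
    """Drop the first ``n_discard`` volumes (default 5, 240 -> 235)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_volumes:
        raise ValueError(
            f"n_discard={n_discard} >= {ts.n_volumes} available volumes"
        )
    if n_discard == 0:
        return ts
    return replace(ts, data=ts.data[n_discard:])


def framewise_displacement(
    motion6: np.ndarray, rotation_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style FD: L1 norm of back-differenced motion parameters.

    Rotations (radians) are converted to millimetres of arc on a sphere of
    radius ``rotation_radius_mm``.  ``fd[0] = 0`` by convention.
    """
    m = np.atleast_2d(np.asarray(motion6, dtype=float))
    if m.shape[0] < 2 or m.shape[1] != 6:
        raise ValueError("motion6 must be (>=2 volumes) x 6")
    if not np.isfinite(m).all():
        bad = int(np.argwhere(~np.isfinite(m).all(axis=1))[0, 0])
        raise ValueError(f"non-finite motion parameters at volume {bad}")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def build_scrub_regressors(
    fd: np.ndarray,
    threshold_mm: float = 0.5,
    n_before: int = 1,
    n_after: int = 2,
) -> np.ndarray:
    """Unit-impulse spike regressors for volumes around FD exceedances.

    Each volume with ``fd > threshold_mm`` flags itself, ``n_before`` volumes
    before and ``n_after`` after (clipped to the run, de-duplicated).  Returns
    a (volumes x n_flagged) 0/1 matrix, one column per flagged volume; empty
    (n x 0) when nothing is flagged.
    """
    fd = np.asarray(fd, dtype=float)
    n = fd.shape[0]
    if n < 1:
        raise ValueError("fd must be non-empty")
    flagged: set[int] = set()
    for t in np.flatnonzero(fd > threshold_mm):
        lo = max(0, t - n_before)
        hi = min(n - 1, t + n_after)
        flagged.update(range(lo, hi + 1))
    cols = sorted(flagged)
    spikes = np.zeros((n, len(cols)))
    for j, t in enumerate(cols):
        spikes[t, j] = 1.0
    return spikes


def expand_friston24(motion6: np.ndarray) -> np.ndarray:
    """Friston 24-parameter expansion: [m, dm, m^2, dm^2].

    The derivative block is the backward difference with a zero first row.
    """
    m = np.atleast_2d(np.asarray(motion6, dtype=float))
    if m.shape[0] < 2 or m.shape[1] != 6:
        raise ValueError("motion6 must be (>=2 volumes) x 6")
    dm = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    return np.hstack([m, dm, m**2, dm**2])


def regress_confounds(
    ts: SubjectTimeSeries, confounders: np.ndarray | None
) -> SubjectTimeSeries:
    """Replace each ROI column by its least-squares residual.

    The design is ``[intercept | confounders]``; exactly collinear confound
    columns are tolerated (minimum-norm solution), so residuals remain
    orthogonal to the retained column space.  With no confounders this is
    demeaning.
    """
    y = ts.data
    n = y.shape[0]
    if confounders is None or np.size(confounders) == 0:
        design = np.ones((n, 1))
    else:
        c = np.atleast_2d(np.asarray(confounders, dtype=float))
        if c.shape[0] != n:
            raise ValueError(
                f"confounder rows ({c.shape[0]}) != time-series rows ({n})"
            )
        if c.shape[1] + 1 > n:
            raise ValueError(
                f"{c.shape[1]} confounders + intercept exceed {n} volumes; "
                "reduce the number of nuisance regressors"
            )
        design = np.hstack([np.ones((n, 1)), c])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return replace(ts, data=y - design @ beta)


def bandpass(
    ts: SubjectTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4
) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass (default 0.01-0.1 Hz).

    Implemented as a forward-backward second-order-section filter, so the
    effective magnitude response is the squared Butterworth response and
    phase is exactly zero.
    """
    fs = 1.0 / ts.tr_seconds
    nyquist = fs / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} >= Nyquist {nyquist:.4g} Hz at TR={ts.tr_seconds} s"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=np.ascontiguousarray(filtered))


def motion_summary(
    confounds: ConfoundSet, rotation_radius_mm: float = 50.0
) -> dict[str, float]:
    """Maximum absolute translation/rotation and mean FD for QC."""
    m = confounds.motion6
    fd = framewise_displacement(m, rotation_radius_mm)
    return {
        "max_abs_translation_mm": float(np.abs(m[:, :3]).max()),
        "max_abs_rotation_deg": float(np.degrees(np.abs(m[:, 3:]).max())),
        "mean_fd_mm": float(fd.mean()),
    }


_QC_FIELDS = (
    "max_abs_translation_mm",
    "max_abs_rotation_deg",
    "mean_fd_mm",
    "moca",
    "gds",
)


def qc_filter(
    subjects: pd.DataFrame,
    moca_min: float = 22,
    gds_max: float = 7,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
    max_mean_fd_mm: float = 0.2,
    motion_rule: str = "conjunction",
) -> tuple[list[str], list[QCReport]]:
    """Apply cohort inclusion criteria; returns (included ids, reports).

    Inclusion requires MoCA >= 22, GDS <= 7, and the motion criterion.  All
    bounds are inclusive.  ``motion_rule`` controls how the motion bounds
    combine: ``"conjunction"`` (default, conservative) requires translation,
    rotation AND mean-FD bounds; ``"disjunction"`` accepts either the
    absolute-motion pair or the mean-FD bound.
    """
    if motion_rule not in {"conjunction", "disjunction"}:
        raise ValueError("motion_rule must be 'conjunction' or 'disjunction'")
    reports: list[QCReport] = []
    included: list[str] = []
    for _, row in subjects.iterrows():
        sid = str(row["subject_id"])
        reasons: list[str] = []
        if any(f not in row or pd.isna(row[f]) for f in _QC_FIELDS):
            reasons.append("missing-data")
            vals = {f: float(row[f]) if f in row and not pd.isna(row[f]) else np.nan
                    for f in _QC_FIELDS}
        else:
            vals = {f: float(row[f]) for f in _QC_FIELDS}
            if vals["moca"] < moca_min:
                reasons.append("cognitive-screen")
            if vals["gds"] > gds_max:
                reasons.append("depression-screen")
            abs_ok = (
                vals["max_abs_translation_mm"] <= max_translation_mm
                and vals["max_abs_rotation_deg"] <= max_rotation_deg
            )
            fd_ok = vals["mean_fd_mm"] <= max_mean_fd_mm
            motion_ok = (abs_ok and fd_ok) if motion_rule == "conjunction" else (
                abs_ok or fd_ok
            )
            if not motion_ok:
                reasons.append("head-motion")
        report = QCReport(
            subject_id=sid,
            max_abs_translation_mm=vals["max_abs_translation_mm"],
            max_abs_rotation_deg=vals["max_abs_rotation_deg"],
            mean_fd_mm=vals["mean_fd_mm"],
            moca=vals["moca"],
            gds=vals["gds"],
            included=not reasons,
            reasons=tuple(reasons),
        )
        reports.append(report)
        if report.included:
            included.append(sid)
    return included, reports


def clean_subject(
    ts: SubjectTimeSeries,
    confounds: ConfoundSet,
    n_discard: int = 5,
    fd_threshold_mm: float = 0.5,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    rotation_radius_mm: float = 50.0,
) -> tuple[SubjectTimeSeries, dict]:
    """Run the full cleaning chain on one subject.

    Order: discard -> FD/spikes -> joint confound regression (tissue/global +
    Friston-24 + spikes) -> band-pass.  Returns the cleaned series and an
    info dict (fd vector, flagged-volume count, regressor count).
    """
    if confounds.motion6.shape[0] != ts.n_volumes:
        raise ValueError("confound rows must match time-series volumes")
    ts = discard_initial(ts, n_discard)
    conf = confounds.drop_initial(n_discard) if n_discard else confounds
    fd = framewise_displacement(conf.motion6, rotation_radius_mm)
    spikes = build_scrub_regressors(fd, threshold_mm=fd_threshold_mm)
    blocks = [expand_friston24(conf.motion6)]
    if conf.tissue_signals is not None:
        blocks.insert(0, conf.tissue_signals)
    if spikes.shape[1]:
        blocks.append(spikes)
    nuisance = np.hstack(blocks)
    ts = regress_confounds(ts, nuisance)
    ts = bandpass(ts, low_hz=low_hz, high_hz=high_hz)
    info = {
        "fd": fd,
        "n_flagged": int(spikes.shape[1]),
        "n_regressors": int(nuisance.shape[1]),
    }
    return ts, info
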