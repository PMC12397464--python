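"""Reading and writing the pipeline's plain-text file formats.

Directory-of-TSV convention: one time-series TSV per subject (header = ROI
names, one row per volume), one whitespace-delimited 6-column motion file
per subject (realignment-parameter dialect), optional per-subject tissue
TSVs, a cohort phenotype table and an atlas label table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasLabels
from .cleaning import ConfoundSet, SubjectTimeSeries
from .networks import ConnectivityMatrix

__all__ = [
    "read_timeseries",
    "read_motion",
    "read_phenotypes",
    "read_atlas",
    "write_connectivity",
    "read_connectivity",
    "list_subjects",
]


def list_subjects(timeseries_dir: str | Path) -> list[str]:
    """Subject ids inferred from time-series file stems, sorted."""
    return sorted(p.stem for p in Path(timeseries_dir).glob("*.tsv"))


def read_timeseries(
    path: str | Path, tr_seconds: float, subject_id: str | None = None
) -> SubjectTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        roi_names=tuple(df.columns),
    )


def read_motion(
    path: str | Path,
    tissue_path: str | Path | None = None,
    subject_id: str | None = None,
    rotation_unit: str = "radians",
) -> ConfoundSet:
    """Read a 6-column motion file (and optional tissue TSV).

    ``rotation_unit`` may be ``"radians"`` (default) or ``"degrees"``;
    degrees are converted on read so the in-memory convention is radians.
    """
    path = Path(path)
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got shape {motion.shape}")
    if rotation_unit == "degrees":
        motion = motion.copy()
        motion[:, 3:] = np.radians(motion[:, 3:])
    elif rotation_unit != "radians":
        raise ValueError("rotation_unit must be 'radians' or 'degrees'")
    tissue = None
    if tissue_path is not None and Path(tissue_path).exists():
        tissue = pd.read_csv(tissue_path, sep="\t").to_numpy(dtype=float)
    return ConfoundSet(
        subject_id=subject_id or path.stem, motion6=motion, tissue_signals=tissue
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if "subject_id" not in df.columns:
        raise ValueError("phenotype table must have a subject_id column")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in phenotype table")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_atlas(path: str | Path) -> AtlasLabels:
    return AtlasLabels.from_frame(pd.read_csv(path, sep="\t"))


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.z, columns=list(cm.roi_names)).to_csv(
        path, sep="\t", index=False
    )


def read_connectivity(path: str | Path, subject_id: str | None = None) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(
        subject_id=subject_id or path.stem,
        z=df.to_numpy(dtype=float),
        roi_names=tuple(df.columns),
    )
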