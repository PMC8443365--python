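"""Readers and writers for every on-disk artifact of the pipeline.

Formats
-------
* 4-D BOLD runs and 3-D maps/masks: NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel.
* Head-motion parameters: whitespace-delimited text, one row per volume, six
  columns — three translations in mm followed by three rotations in radians
  (a ``rotations="degrees"`` switch accepts the other common dialect).
* Phenotypes: UTF-8 CSV with a header row.
* Cluster reports: TSV with one row per suprathreshold cluster (label, peak
  world coordinates in mm, voxel count, peak t, direction, corrected p).

Voxel indices are 0-based internally; peak coordinates in cluster reports are
world-space (affine applied), matching the MNI-style convention of
neuroimaging result tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError

GROUP_LABELS = ("patient", "control")

PHENOTYPE_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "illness_duration",
    "ybocs_total",
    "ybocs_obsession",
    "ybocs_compulsion",
    "hamd",
    "hama",
]

CLUSTER_TABLE_COLUMNS = [
    "label",
    "peak_x",
    "peak_y",
    "peak_z",
    "n_voxels",
    "peak_t",
    "direction",
    "corrected_p",
]


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------


@dataclass
class BoldRun:
    """One subject's 4-D BOLD time series.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD intensities, ``t >= 2``, all finite.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    subject_id : str
        Identifier used in filenames and reports.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise DataError(
                f"BOLD run for {self.subject_id or '<unnamed>'} must be 4-D, "
                f"got {self.data.ndim}-D"
            )
        if self.data.shape[3] < 2:
            raise DataError("BOLD run needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise DataError("BOLD run contains non-finite values")
        if not self.tr_seconds > 0:
            raise DataError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.affine.shape != (4, 4):
            raise DataError("affine must be 4x4")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths of one voxel in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MaskVolume:
    """3-D boolean mask (e.g. gray matter) sharing the grid of the runs."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError(f"mask must be 3-D, got {self.data.ndim}-D")
        if self.n_voxels < 1:
            raise DataError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_matches(self, run: BoldRun) -> None:
        if run.spatial_shape != self.data.shape:
            raise DataError(
                f"mask shape {self.data.shape} does not match run shape "
                f"{run.spatial_shape} for subject {run.subject_id!r}"
            )


@dataclass
class SubjectRecord:
    """One phenotype row: group membership, demographics and clinical scores.

    Clinical scales: Y-BOCS (obsessive-compulsive severity, total plus
    obsession/compulsion subscales), HAMD (depression), HAMA (anxiety).
    ``illness_duration`` is months since onset and applies to patients only.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    illness_duration: float | None = None
    ybocs_total: float | None = None
    ybocs_obsession: float | None = None
    ybocs_compulsion: float | None = None
    hamd: float | None = None
    hama: float | None = None
    bold_path: str | None = None
    motion_path: str | None = None
    nuisance_path: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise DataError(
                f"subject {self.subject_id!r}: unknown group label {self.group!r} "
                f"(expected one of {GROUP_LABELS})"
            )
        if self.ybocs_total is not None and not np.isnan(self.ybocs_total):
            if self.ybocs_total < 0:
                raise DataError(f"subject {self.subject_id!r}: negative Y-BOCS total")


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def read_bold(path: str | Path, tr_seconds: float | None = None) -> BoldRun:
    """Load a 4-D NIfTI BOLD run.

    The repetition time is taken from the header's 4th zoom unless
    ``tr_seconds`` overrides it.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise DataError(f"cannot read NIfTI header of {path}: {exc}") from exc
    if img.ndim != 4:
        raise DataError(f"{path} is {img.ndim}-D; a 4-D BOLD run is required")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_seconds <= 0:
            raise DataError(
                f"{path} has no repetition time in its header; pass tr_seconds"
            )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return BoldRun(
        data=data,
        tr_seconds=float(tr_seconds),
        affine=img.affine,
        subject_id=path.name.split("_")[0].removeprefix("sub-"),
    )


def write_bold(run: BoldRun, path: str | Path) -> Path:
    """Write a run as NIfTI-1, storing the TR in the header zooms."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr_seconds
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def write_volume(
    values: np.ndarray, affine: np.ndarray, path: str | Path
) -> Path:
    """Write a 3-D map (degree map, t-map, mask, ...) as NIfTI-1."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise DataError(f"write_volume expects a 3-D array, got {values.ndim}-D")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if values.dtype == bool else np.float32
    img = nib.Nifti1Image(values.astype(dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D NIfTI map; returns ``(data, affine)``."""
    path = Path(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DataError(f"{path} is {img.ndim}-D; a 3-D volume is required")
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def read_mask(path: str | Path) -> MaskVolume:
    data, affine = read_volume(path)
    return MaskVolume(data=data > 0, affine=affine)


# ---------------------------------------------------------------------------
# Motion and nuisance text files
# ---------------------------------------------------------------------------


def read_motion(path: str | Path, rotations: str = "radians") -> np.ndarray:
    """Load a 6-column motion file (one row per volume).

    Columns 0-2 are translations in mm, 3-5 rotations. ``rotations`` names
    the unit on disk ("radians", the native dialect, or "degrees"); the
    returned array always holds radians.
    """
    path = Path(path)
    try:
        motion = np.loadtxt(str(path), ndmin=2)
    except Exception as exc:
        raise DataError(f"cannot parse motion file {path}: {exc}") from exc
    if motion.shape[1] != 6:
        raise DataError(
            f"motion file {path} has {motion.shape[1]} columns; 6 expected"
        )
    if rotations == "degrees":
        motion = motion.copy()
        motion[:, 3:] = np.deg2rad(motion[:, 3:])
    elif rotations != "radians":
        raise DataError(f"unknown rotation unit {rotations!r}")
    return motion


def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError("motion array must be (n_volumes, 6)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(str(path), motion, fmt="%.10g")
    return path


def read_nuisance(path: str | Path) -> pd.DataFrame:
    """Load per-volume nuisance series (wm, csf columns) from TSV."""
    df = pd.read_csv(path, sep="\t")
    for col in ("wm", "csf"):
        if col not in df.columns:
            raise DataError(f"nuisance file {path} lacks a {col!r} column")
    return df


def write_nuisance(wm: np.ndarray, csf: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"wm": wm, "csf": csf}).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(csv_path: str | Path) -> list[SubjectRecord]:
    """Load and validate the phenotype table.

    Raises on duplicate subject ids or unknown group labels; a control row
    carrying an illness duration triggers a warning and the value is dropped
    (the field is undefined for controls).
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{csv_path}: missing phenotype columns {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"{csv_path}: duplicated subject ids {dupes}")
    records = []
    for _, row in df.iterrows():
        duration = row["illness_duration"]
        if row["group"] == "control" and pd.notna(duration):
            warnings.warn(
                f"control subject {row['subject_id']!r} has an illness_duration "
                "value; ignored",
                stacklevel=2,
            )
            duration = np.nan
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                illness_duration=None if pd.isna(duration) else float(duration),
                ybocs_total=_opt(row, "ybocs_total"),
                ybocs_obsession=_opt(row, "ybocs_obsession"),
                ybocs_compulsion=_opt(row, "ybocs_compulsion"),
                hamd=_opt(row, "hamd"),
                hama=_opt(row, "hama"),
                bold_path=_opt_str(row, "bold_path"),
                motion_path=_opt_str(row, "motion_path"),
                nuisance_path=_opt_str(row, "nuisance_path"),
            )
        )
    return records


def _opt(row: pd.Series, col: str) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def _opt_str(row: pd.Series, col: str) -> str | None:
    if col not in row or pd.isna(row[col]):
        return None
    return str(row[col])


def phenotypes_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "education": r.education,
                "illness_duration": np.nan
                if r.illness_duration is None
                else r.illness_duration,
                "ybocs_total": np.nan if r.ybocs_total is None else r.ybocs_total,
                "ybocs_obsession": np.nan
                if r.ybocs_obsession is None
                else r.ybocs_obsession,
                "ybocs_compulsion": np.nan
                if r.ybocs_compulsion is None
                else r.ybocs_compulsion,
                "hamd": np.nan if r.hamd is None else r.hamd,
                "hama": np.nan if r.hama is None else r.hama,
                "bold_path": r.bold_path,
                "motion_path": r.motion_path,
                "nuisance_path": r.nuisance_path,
            }
        )
    return pd.DataFrame(rows)


def write_phenotypes(records: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    phenotypes_to_frame(records).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Cluster tables
# ---------------------------------------------------------------------------


def write_cluster_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cluster report TSV (label, peak x/y/z mm, voxel count, peak t,
    direction, corrected p)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.loc[:, CLUSTER_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLUSTER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing cluster-table columns {missing}")
    return df
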