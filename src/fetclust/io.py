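"""Reading and writing of on-disk artifacts.

Volumes travel as NIfTI-1 (``.nii``/``.nii.gz``) via nibabel.  Frame timing
is not standardized in the NIfTI header, so every dynamic volume is
accompanied by a BIDS-like JSON sidecar::

    {"FrameTimesStart": [0, 5, ...], "FrameDuration": [5, 5, ...]}

with all times in **minutes** post-injection.  Cohort feature tables are
plain CSV (header row, RFC 4180); learned centroid sets are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError, GeometryError, ValidationError

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "CohortTable",
    "read_dynamic",
    "write_dynamic",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort",
    "write_cohort",
    "read_centroids",
    "write_centroids",
]

#: canonical cohort CSV columns (survival columns are optional)
COHORT_COLUMNS = [
    "id", "histology", "mib1", "idh1", "who_grade",
    "pct_c1", "pct_c2", "pct_c3",
    "suv_max", "suv_mean", "tbr_max", "tbr_mean",
    "ttp_min", "slope_suv_per_h",
]
SURVIVAL_COLUMNS = ["pfs_months", "pfs_event", "os_months", "os_event"]


@dataclass(frozen=True)
class FrameSchedule:
    """Start time and duration of every dynamic frame, in minutes.

    The default clinical protocol is 10 frames of 5 min spanning 0-50 min
    post-injection.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_times, dtype=float)
        dur = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", start)
        object.__setattr__(self, "durations", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValidationError("start_times and durations must be 1-D and equal length")
        if start.size == 0:
            raise ValidationError("schedule must have at least one frame")
        if np.any(np.diff(start) <= 0):
            raise ValidationError("start_times must be strictly increasing")
        if np.any(dur <= 0):
            raise ValidationError("durations must be positive")

    @classmethod
    def default(cls, n_frames: int = 10, frame_minutes: float = 5.0) -> "FrameSchedule":
        start = np.arange(n_frames) * frame_minutes
        return cls(start, np.full(n_frames, frame_minutes))

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in minutes (used for slope regression)."""
        return self.start_times + self.durations / 2.0

    @property
    def end_time(self) -> float:
        return float(self.start_times[-1] + self.durations[-1])

    @property
    def is_contiguous(self) -> bool:
        return bool(np.allclose(self.start_times[1:],
                                self.start_times[:-1] + self.durations[:-1]))

    def frames_in_window(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of frames whose start time lies in ``[window[0], window[1])``."""
        lo, hi = window
        return np.flatnonzero((self.start_times >= lo) & (self.start_times < hi))

    def to_dict(self) -> dict:
        return {"FrameTimesStart": self.start_times.tolist(),
                "FrameDuration": self.durations.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        try:
            return cls(np.asarray(d["FrameTimesStart"], float),
                       np.asarray(d["FrameDuration"], float))
        except KeyError as exc:  # pragma: no cover - defensive
            raise FormatError(f"timing sidecar missing key {exc}") from exc


@dataclass
class DynamicImage:
    """A 4-D dynamic PET volume in SUV units.

    ``voxels`` is indexed ``(x, y, z, frame)``; ``voxel_size`` is the edge
    length of a voxel in mm per axis; ``affine`` is the NIfTI voxel-to-world
    matrix (a diagonal scaling by default).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValidationError(f"expected 4D volume, got {self.voxels.ndim}D")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValidationError(
                f"frame count {self.voxels.shape[3]} does not match schedule "
                f"length {self.schedule.n_frames}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("SUV volume contains non-finite values")
        if np.any(self.voxels < 0):
            raise ValidationError("SUV values must be non-negative")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass
class CohortTable:
    """A validated per-patient feature table (one row per patient)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("cohort table is empty")
        if df["id"].duplicated().any():
            raise ValidationError("patient ids must be unique")
        for col in ("pct_c1", "pct_c2", "pct_c3"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"non-numeric value in column {col}")
            if ((vals < 0) | (vals > 100)).any():
                raise ValidationError(f"{col} outside [0, 100]")
            df[col] = vals.astype(float)
        bad = ~df["idh1"].isin(["+", "-"])
        if bad.any():
            raise ValidationError("idh1 column must be '+' or '-'")
        df["idh1_mutant"] = df["idh1"] == "+"

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_survival(self) -> bool:
        return all(c in self.frame.columns for c in SURVIVAL_COLUMNS)


# ---------------------------------------------------------------------------
# dynamic volumes

def read_dynamic(path_nifti, path_sidecar) -> DynamicImage:
    """Load a 4-D SUV NIfTI plus its frame-timing JSON sidecar."""
    img = nib.load(str(path_nifti))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise FormatError(f"expected 4D NIfTI, got {data.ndim}D")
    with open(path_sidecar) as fh:
        schedule = FrameSchedule.from_dict(json.load(fh))
    if data.shape[3] != schedule.n_frames:
        raise FormatError(
            f"sidecar declares {schedule.n_frames} frames but image has "
            f"{data.shape[3]}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(data, voxel_size, schedule, affine=np.asarray(img.affine))


def write_dynamic(img: DynamicImage, path_nifti, path_sidecar) -> None:
    nii = nib.Nifti1Image(img.voxels.astype(np.float32), img.affine)
    nii.header.set_zooms((*img.voxel_size, 1.0))
    nib.save(nii, str(path_nifti))
    with open(path_sidecar, "w") as fh:
        json.dump(img.schedule.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# static volumes and masks

def read_volume(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Return ``(data, voxel_size, affine)`` for a 3-D NIfTI."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FormatError(f"expected 3D NIfTI, got {data.ndim}D")
    return data, tuple(float(z) for z in img.header.get_zooms()[:3]), np.asarray(img.affine)


def write_volume(data: np.ndarray, voxel_size, path, affine=None,
                 dtype=np.float32) -> None:
    if affine is None:
        affine = np.diag([*voxel_size, 1.0])
    nii = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nii.header.set_zooms(tuple(voxel_size))
    nib.save(nii, str(path))


def write_mask(mask, path, reference_shape=None) -> None:
    """Write a tumor mask as a 0/1 uint8 NIfTI.

    Segmentation provenance (z threshold, minimum cluster size, dilation
    iterations, connectivity) is stored in a JSON sidecar next to the
    NIfTI so it survives round trips uncorrupted by the 80-char header
    description limit.
    """
    from .segmentation import TumorMask  # deferred: avoids import cycle

    if not isinstance(mask, TumorMask):
        raise ValidationError("write_mask expects a TumorMask")
    if reference_shape is not None and mask.voxels.shape != tuple(reference_shape):
        raise GeometryError(
            f"mask shape {mask.voxels.shape} does not match reference "
            f"{tuple(reference_shape)}")
    write_volume(mask.voxels.astype(np.uint8), mask.voxel_size, path,
                 affine=mask.affine, dtype=np.uint8)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(mask.params, fh, indent=1)


def read_mask(path):
    from .segmentation import TumorMask  # deferred: avoids import cycle

    data, voxel_size, affine = read_volume(path)
    sidecar = _sidecar_path(path)
    params = {}
    if Path(sidecar).exists():
        with open(sidecar) as fh:
            params = json.load(fh)
    return TumorMask(data > 0.5, params=params, voxel_size=voxel_size,
                     affine=affine)


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


# ---------------------------------------------------------------------------
# cohort tables

def read_cohort(path) -> CohortTable:
    """Read and validate a cohort feature CSV.

    IDH1 status is encoded ``"+"``/``"-"`` in the file; a boolean
    ``idh1_mutant`` column is derived on load.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError("cohort CSV is empty") from exc
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    df = cohort.frame.drop(columns=["idh1_mutant"], errors="ignore")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# centroid sets

def write_centroids(centroids, path) -> None:
    from .tac import CentroidSet  # deferred: avoids import cycle

    if not isinstance(centroids, CentroidSet):
        raise ValidationError("write_centroids expects a CentroidSet")
    payload = {
        "curves": centroids.curves.tolist(),
        "semantic_labels": centroids.semantic_labels,
        "metadata": centroids.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_centroids(path):
    from .tac import CentroidSet  # deferred: avoids import cycle

    with open(path) as fh:
        payload = json.load(fh)
    labels = payload.get("semantic_labels")
    if labels is not None:
        labels = {int(k): v for k, v in labels.items()}
    return CentroidSet(np.asarray(payload["curves"], float),
                       semantic_labels=labels,
                       metadata=payload.get("metadata", {}))
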