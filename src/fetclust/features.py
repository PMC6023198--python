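"""Per-patient imaging features.

Two families of features are computed from a segmented dynamic scan:

* **centroid proportions** — the percentage of tumor voxels whose TAC is
  assigned to each of the three canonical centroids; these are the
  voxel-wise kinetic summary the clustering produces;
* **conventional parameters** — SUVmax/SUVmean on the late static image,
  tumor-to-brain ratios (TBRmax/TBRmean) against a contralateral normal
  reference region, time-to-peak (TTP) and the late-phase slope of the
  tumor mean TAC.

TTP and slope follow the usual clinical conventions for amino-acid PET:
TTP is the start time of the frame holding the maximum of the tumor mean
TAC (first frame on ties), and the slope is the OLS slope of the mean
TAC over 20-50 min post-injection, expressed in SUV/hour.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ValidationError
from .io import DynamicImage, FrameSchedule
from .segmentation import StaticImage, TumorMask
from .tac import VoxelAssignment

__all__ = [
    "FeatureRecord",
    "centroid_proportions",
    "tumor_suv",
    "tbr",
    "time_to_peak",
    "late_slope",
    "mean_tumor_tac",
    "mirror_reference_mask",
    "build_feature_record",
]


@dataclass
class FeatureRecord:
    """One patient's feature row (one line of the cohort CSV)."""

    patient_id: str
    pct_c1: float
    pct_c2: float
    pct_c3: float
    suv_max: float
    suv_mean: float
    ttp_min: float
    slope_suv_per_h: float
    tbr_max: float | None = None
    tbr_mean: float | None = None
    idh1_mutant: bool | None = None
    pfs_months: float | None = None
    pfs_event: bool | None = None
    os_months: float | None = None
    os_event: bool | None = None

    def __post_init__(self):
        total = self.pct_c1 + self.pct_c2 + self.pct_c3
        if abs(total - 100.0) > 0.1:
            raise ValidationError(
                f"centroid percentages sum to {total:.3f}, expected 100 +/- 0.1")
        for name in ("tbr_max", "tbr_mean"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


def centroid_proportions(assign: VoxelAssignment) -> tuple[float, float, float]:
    """Percentage of voxels carrying each semantic label (#1, #2, #3)."""
    if assign.labels.size == 0:
        raise ValidationError("no voxels to tally")
    if assign.labels.max(initial=1) > 3:
        raise ValidationError("proportions are defined for the 3-centroid model")
    v = assign.labels.size
    return tuple(100.0 * float((assign.labels == c).sum()) / v for c in (1, 2, 3))


def tumor_suv(img: StaticImage | DynamicImage, mask: TumorMask,
              window: tuple[float, float] = (40.0, 50.0)) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the mask on the late static image.

    A dynamic image is first collapsed to its 40-50 min static; passing a
    StaticImage uses it as-is.
    """
    if isinstance(img, DynamicImage):
        from .segmentation import static_from_dynamic
        img = static_from_dynamic(img, window)
    if mask.voxels.shape != img.voxels.shape:
        raise ValidationError("mask and image geometry differ")
    if mask.is_empty:
        raise ValidationError("empty mask: no tumor voxels")
    vals = img.voxels[mask.voxels]
    return float(vals.max()), float(vals.mean())


def tbr(suv_max: float, suv_mean: float, ref_mean: float) -> tuple[float, float]:
    """Tumor-to-brain ratios: tumor SUVmax and SUVmean over the reference mean."""
    if ref_mean <= 0:
        raise ValidationError("reference-region mean SUV must be positive")
    return suv_max / ref_mean, suv_mean / ref_mean


def mean_tumor_tac(img: DynamicImage, mask: TumorMask) -> np.ndarray:
    """Tumor mean TAC: the mask-average SUV per frame (raw scale)."""
    if mask.voxels.shape != img.shape:
        raise ValidationError("mask and image geometry differ")
    if mask.is_empty:
        raise ValidationError("empty mask: no tumor voxels")
    return img.voxels[mask.voxels].mean(axis=0)


def time_to_peak(mean_tac: np.ndarray, schedule: FrameSchedule) -> float:
    """Minutes from acquisition start to the frame of maximum SUV.

    Returns the *start time* of the peak frame (first occurrence on
    ties), so a 10 x 5 min protocol yields values in {0, 5, ..., 45}.
    """
    mean_tac = np.asarray(mean_tac, float)
    if mean_tac.size != schedule.n_frames:
        raise ValidationError("TAC length does not match schedule")
    return float(schedule.start_times[int(np.argmax(mean_tac))])


def late_slope(mean_tac: np.ndarray, schedule: FrameSchedule,
               window: tuple[float, float] = (20.0, 50.0)) -> float:
    """OLS slope of the tumor mean TAC over the late window, in SUV/hour.

    Frame mid-times are the regressor; with uniform frame spacing the
    slope is identical whether start or mid times are used.
    """
    mean_tac = np.asarray(mean_tac, float)
    if mean_tac.size != schedule.n_frames:
        raise ValidationError("TAC length does not match schedule")
    idx = schedule.frames_in_window(window)
    if idx.size < 2:
        raise ValidationError(
            f"late-slope window {window} covers {idx.size} frame(s); need >= 2")
    t_hours = schedule.mid_times[idx] / 60.0
    return float(np.polyfit(t_hours, mean_tac[idx], 1)[0])


def mirror_reference_mask(mask: TumorMask, erosion_iterations: int = 1) -> TumorMask:
    """Fallback reference region: the tumor's bounding box mirrored
    across the mid-sagittal plane (x axis) and eroded.

    A crescent ROI drawn in the contralateral centrum semiovale by an
    operator is the clinical standard; this automatic surrogate only
    guarantees a contralateral, tumor-free sample of normal brain on
    phantoms and should be replaced by a curated mask on real data.
    """
    from scipy import ndimage

    if mask.is_empty:
        raise ValidationError("cannot mirror an empty mask")
    box = np.zeros_like(mask.voxels)
    xs, ys, zs = np.where(mask.voxels)
    box[xs.min():xs.max() + 1, ys.min():ys.max() + 1, zs.min():zs.max() + 1] = True
    mirrored = box[::-1, :, :].copy()
    mirrored &= ~mask.voxels  # never sample tumor
    if erosion_iterations > 0:
        mirrored = ndimage.binary_erosion(
            mirrored, ndimage.generate_binary_structure(3, 1),
            iterations=erosion_iterations)
    if not mirrored.any():
        raise ValidationError("mirrored reference region is empty")
    return TumorMask(mirrored, params={"kind": "mirrored_reference"},
                     voxel_size=mask.voxel_size, affine=mask.affine)


def build_feature_record(patient_id, assign: VoxelAssignment,
                         img: DynamicImage, mask: TumorMask,
                         ref_mask: TumorMask | None = None,
                         static_window: tuple[float, float] = (40.0, 50.0),
                         slope_window: tuple[float, float] = (20.0, 50.0),
                         **extra) -> FeatureRecord:
    """Assemble one validated feature row from pipeline intermediates.

    When no reference region is available the TBR fields stay ``None``
    (flagged by their absence in the output CSV).
    """
    from .segmentation import static_from_dynamic

    pct = centroid_proportions(assign)
    static = static_from_dynamic(img, static_window)
    suv_max, suv_mean = tumor_suv(static, mask)
    tac = mean_tumor_tac(img, mask)
    record = dict(
        patient_id=str(patient_id),
        pct_c1=pct[0], pct_c2=pct[1], pct_c3=pct[2],
        suv_max=suv_max, suv_mean=suv_mean,
        ttp_min=time_to_peak(tac, img.schedule),
        slope_suv_per_h=late_slope(tac, img.schedule, slope_window),
    )
    if ref_mask is not None:
        ref_vals = static.voxels[ref_mask.voxels]
        if ref_vals.size == 0:
            raise ValidationError("reference mask selects no voxels")
        t_max, t_mean = tbr(suv_max, suv_mean, float(ref_vals.mean()))
        record.update(tbr_max=t_max, tbr_mean=t_mean)
    record.update(extra)
    return FeatureRecord(**record)
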