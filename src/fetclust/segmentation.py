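"""Z-score template construction and tumor mask generation.

The segmentation follows the semi-automatic scheme used for amino-acid
PET of gliomas: a late static uptake image (40-50 min) is compared
voxelwise against a template built from visually normal scans, the
resulting Z-score map is thresholded (Z > 2.5), small connected
components are discarded (< 250 voxels), and the surviving clusters are
dilated with a 6-connected 3x3x3 cross for 2 iterations so that
adjacent, borderline voxels are not missed.

All volumes entering these functions are assumed to live on a common
voxel grid (spatial normalization is upstream of this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError, ValidationError
from .io import DynamicImage

__all__ = [
    "StaticImage",
    "NormalTemplate",
    "TumorMask",
    "static_from_dynamic",
    "smooth_gaussian",
    "fwhm_to_sigma",
    "build_template",
    "zscore_map",
    "make_tumor_mask",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma = fwhm / FWHM_FACTOR


@dataclass
class StaticImage:
    """A 3-D late-uptake SUV image (mean over an acquisition window)."""

    voxels: np.ndarray
    window: tuple[float, float] = (40.0, 50.0)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError("static image must be 3D")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])


@dataclass
class NormalTemplate:
    """Voxelwise mean and SD of late static uptake across normal scans.

    ``sd_floor`` is the minimum SD substituted where the normals are
    near-constant, preventing Z-score blow-ups; by default it is the 5th
    percentile of the nonzero SDs.
    """

    mean_vol: np.ndarray
    sd_vol: np.ndarray
    n_subjects: int
    sd_floor: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.mean_vol = np.asarray(self.mean_vol, float)
        self.sd_vol = np.asarray(self.sd_vol, float)
        if self.mean_vol.shape != self.sd_vol.shape:
            raise GeometryError("template mean and SD volumes differ in shape")
        if np.any(self.sd_vol < 0):
            raise ValidationError("template SD must be non-negative")
        if self.n_subjects < 2:
            raise ValidationError("template needs at least 2 subjects")
        if self.sd_floor is None:
            nonzero = self.sd_vol[self.sd_vol > 0]
            floor = float(np.percentile(nonzero, 5)) if nonzero.size else 1e-6
            self.sd_floor = max(floor, 1e-12)


@dataclass
class TumorMask:
    """Boolean tumor mask plus the parameters that produced it."""

    voxels: np.ndarray
    params: dict = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be 3D")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def non_segmentable(self) -> bool:
        """True when no supra-threshold cluster survived the size filter."""
        return self.is_empty

    def volume_ml(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size)) / 1000.0


def static_from_dynamic(img: DynamicImage,
                        window: tuple[float, float] = (40.0, 50.0)) -> StaticImage:
    """Average the frames whose start time falls in ``[window)``.

    The mean (rather than the literal sum) keeps the result in SUV; Z-score
    maps and uptake ratios are unaffected by this scale choice.
    """
    idx = img.schedule.frames_in_window(window)
    if idx.size == 0:
        raise ValidationError(
            f"no frame starts within window {window} "
            f"(acquisition spans 0-{img.schedule.end_time:g} min)")
    return StaticImage(img.voxels[..., idx].mean(axis=3), window=tuple(window),
                       voxel_size=img.voxel_size, affine=img.affine)


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return fwhm_mm / FWHM_FACTOR / np.asarray(voxel_size_mm, float)


def smooth_gaussian(vol: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Isotropic (in mm) Gaussian smoothing of a 3-D volume."""
    if fwhm_mm <= 0:
        raise ValidationError("FWHM must be positive")
    return ndimage.gaussian_filter(np.asarray(vol, float),
                                   sigma=fwhm_to_sigma(fwhm_mm, voxel_size_mm))


def build_template(statics: list[StaticImage]) -> NormalTemplate:
    """Voxelwise mean and sample SD (ddof=1) over normal static images."""
    if len(statics) < 2:
        raise ValidationError("need at least 2 normal scans for a template")
    shapes = {s.voxels.shape for s in statics}
    if len(shapes) > 1:
        raise GeometryError(f"normal scans have differing shapes: {shapes}")
    stack = np.stack([s.voxels for s in statics], axis=0)
    return NormalTemplate(stack.mean(axis=0), stack.std(axis=0, ddof=1),
                          n_subjects=len(statics))


def zscore_map(static: StaticImage, tmpl: NormalTemplate) -> np.ndarray:
    """Voxelwise Z = (patient - template mean) / max(template SD, floor)."""
    if static.voxels.shape != tmpl.mean_vol.shape:
        raise GeometryError(
            f"static {static.voxels.shape} vs template {tmpl.mean_vol.shape}")
    sd = np.maximum(tmpl.sd_vol, tmpl.sd_floor)
    return (static.voxels - tmpl.mean_vol) / sd


def make_tumor_mask(z: np.ndarray,
                    z_threshold: float = 2.5,
                    min_cluster_voxels: int = 250,
                    dilation_iterations: int = 2,
                    connectivity: int = 2,
                    voxel_size=(2.0, 2.0, 2.0),
                    affine=None) -> TumorMask:
    """Threshold a Z map, keep large connected clusters, dilate.

    Voxels with Z > ``z_threshold`` are labeled into connected components
    (``connectivity`` in the scipy sense: 1 = faces only, 2 = faces+edges,
    i.e. 18-connectivity, the default). Components smaller than
    ``min_cluster_voxels`` are dropped; the union of the survivors is
    binary-dilated with the 3x3x3 connectivity-1 cross, repeated
    ``dilation_iterations`` times.

    An empty result is legal: the scan is flagged non-segmentable rather
    than raising, mirroring how visually normal scans are excluded from
    a cohort.
    """
    z = np.asarray(z, float)
    if not np.all(np.isfinite(z)):
        raise ValidationError("Z map contains non-finite values")
    params = {"z_threshold": z_threshold,
              "min_cluster_voxels": min_cluster_voxels,
              "dilation_iterations": dilation_iterations,
              "connectivity": connectivity}
    above = z > z_threshold
    label_struct = ndimage.generate_binary_structure(3, connectivity)
    labels, n_comp = ndimage.label(above, structure=label_struct)
    keep = np.zeros_like(above)
    if n_comp:
        sizes = np.bincount(labels.ravel())
        big = np.flatnonzero(sizes >= min_cluster_voxels)
        big = big[big != 0]  # 0 is background
        if big.size:
            keep = np.isin(labels, big)
    if keep.any() and dilation_iterations > 0:
        cross = ndimage.generate_binary_structure(3, 1)
        keep = ndimage.binary_dilation(keep, structure=cross,
                                       iterations=dilation_iterations)
    return TumorMask(keep, params=params, voxel_size=tuple(voxel_size),
                     affine=affine)
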