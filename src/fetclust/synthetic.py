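"""Synthetic dynamic PET phantoms and cohorts with known ground truth.

Every stage of the pipeline can be exercised without patient data:

* :func:`make_archetype_curves` builds three smooth TAC archetypes on
  the frame grid — slow accumulation (#1), rapid rise with slow decline
  (#2), rapid rise with rapid washout (#3);
* :func:`simulate_tacs` draws noisy voxel TACs from those archetypes
  with known labels (the clustering test bed);
* :func:`simulate_phantom` embeds an ellipsoidal lesion whose voxels
  follow an archetype mixture inside a noisy uniform brain background,
  returning the 4-D image and the voxelwise true labels;
* :func:`simulate_cohort` draws per-patient feature rows with an
  IDH1-linked composition shift and exponential survival with a benefit
  for centroid-#1-dominant tumors.

Everything is deterministic given the seed.  The phantoms deliberately
omit PET physics (attenuation, scatter, partial volume, reconstruction
texture): they validate the *algorithms*, not scanner realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io import CohortTable, DynamicImage, FrameSchedule
from .tac import _ols_slope

__all__ = [
    "ArchetypeParams",
    "Lesion",
    "PhantomSpec",
    "make_archetype_curves",
    "simulate_tacs",
    "simulate_phantom",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ArchetypeParams:
    """Piecewise-linear TAC archetype knots, per curve.

    Each curve is defined by its SUV at the first frame mid-time
    (``start``), at ``peak_time`` (``peak``) and at the last frame
    mid-time (``end``), linearly interpolated in between.  Defaults give
    a slow riser, a moderate riser with slow decline and a fast riser
    with rapid washout against a background of about 1 SUV.
    """

    start: tuple[float, float, float] = (0.4, 0.5, 0.6)
    peak_time: tuple[float, float, float] = (47.5, 12.5, 7.5)
    peak: tuple[float, float, float] = (2.2, 2.4, 2.6)
    end: tuple[float, float, float] = (2.2, 2.0, 1.4)


def make_archetype_curves(params: ArchetypeParams | None,
                          schedule: FrameSchedule) -> np.ndarray:
    """Three archetype TACs (rows) evaluated at the frame mid-times.

    Raises when the parameters violate the shape taxonomy: the late
    (20-50 min) OLS slope must be positive for curve 1, negative for
    curves 2 and 3 with curve 3 steeper, and all SUVs non-negative.
    """
    params = params or ArchetypeParams()
    t = schedule.mid_times
    curves = np.empty((3, t.size))
    for i in range(3):
        knots_t = [t[0], params.peak_time[i], t[-1]]
        knots_v = [params.start[i], params.peak[i], params.end[i]]
        if not (t[0] <= params.peak_time[i] <= t[-1]):
            raise ValidationError("peak_time outside the acquisition span")
        # collapse duplicate knots when the peak sits on an endpoint
        pts = sorted(set(zip(knots_t, knots_v)))
        curves[i] = np.interp(t, [p[0] for p in pts], [p[1] for p in pts])
    if np.any(curves < 0):
        raise ValidationError("archetype curves must be non-negative")
    late = schedule.frames_in_window((20.0, 50.0))
    slopes = np.array([_ols_slope(t[late], c[late]) for c in curves])
    if not (slopes[0] > 0 and slopes[2] < slopes[1] < 0):
        raise ValidationError(
            f"late slopes {slopes} violate the archetype taxonomy "
            "(need s1 > 0 and s3 < s2 < 0)")
    return curves


def simulate_tacs(n_per_archetype: int = 100, noise_sd: float = 0.2,
                  schedule: FrameSchedule | None = None,
                  params: ArchetypeParams | None = None,
                  weights=None, n_total: int | None = None,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Noisy voxel TACs drawn from the three archetypes, with labels.

    Either ``n_per_archetype`` (balanced draw) or ``weights`` plus
    ``n_total`` (multinomial mixture) fixes the composition.  Returns
    ``(V x T raw-SUV matrix, V labels in {1,2,3})``.
    """
    schedule = schedule or FrameSchedule.default()
    curves = make_archetype_curves(params, schedule)
    rng = np.random.default_rng(seed)
    if weights is not None:
        w = np.asarray(weights, float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("weights must be non-negative and sum to 1")
        if n_total is None:
            raise ValidationError("n_total is required with weights")
        labels = rng.choice(3, size=n_total, p=w) + 1
    else:
        labels = np.repeat([1, 2, 3], n_per_archetype)
    X = curves[labels - 1] + rng.normal(0.0, noise_sd,
                                        size=(labels.size, schedule.n_frames))
    return np.clip(X, 0.0, None), labels


@dataclass(frozen=True)
class Lesion:
    """Ellipsoidal lesion: center (voxel indices), radii (mm), archetype
    mixture weights."""

    center: tuple[int, int, int]
    radii_mm: tuple[float, float, float]
    weights: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("lesion weights must be >= 0 and sum to 1")


@dataclass
class PhantomSpec:
    """Geometry and noise model of a synthetic 4-D brain."""

    shape: tuple[int, int, int] = (60, 48, 48)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.0
    background_subject_sd: float = 0.15  # between-subject level shift
    noise_sd: float = 0.2                # per voxel-frame SUV noise
    # one lateralized ~24 mL lesion (typical glioma volume); keeping it off
    # the mid-sagittal plane leaves contralateral brain free for the
    # mirrored reference region
    lesions: list[Lesion] = field(default_factory=lambda: [
        Lesion(center=(18, 24, 24), radii_mm=(20.0, 18.0, 16.0))])
    seed: int = 0
    schedule: FrameSchedule = field(default_factory=FrameSchedule.default)
    archetypes: ArchetypeParams = field(default_factory=ArchetypeParams)


def _ellipsoid_mask(shape, center, radii_mm, voxel_size) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, float)
    for g, c, r, vz in zip(grids, center, radii_mm, voxel_size):
        if r <= 0:
            raise ValidationError("lesion radii must be positive")
        acc = acc + ((g - c) * vz / r) ** 2
    return acc <= 1.0


def _sector_labels(inside: np.ndarray, lesion: Lesion,
                   rng: np.random.Generator) -> np.ndarray:
    """Archetype label per lesion voxel, in contiguous angular sectors.

    Tumors show spatially coherent kinetic subregions, so the mixture is
    realized as wedges around the lesion's z axis (random orientation)
    whose voxel counts match the mixture weights exactly, rather than as
    an i.i.d. per-voxel draw that spatial smoothing would homogenize.
    """
    coords = np.argwhere(inside)
    theta = np.arctan2(coords[:, 1] - lesion.center[1],
                       coords[:, 0] - lesion.center[0])
    theta = (theta + rng.uniform(0.0, 2 * np.pi)) % (2 * np.pi)
    order = np.argsort(theta, kind="stable")
    n = coords.shape[0]
    counts = np.floor(np.asarray(lesion.weights) * n).astype(int)
    counts[0] += n - counts.sum()  # remainder to the first archetype
    labels = np.empty(n, dtype=np.int8)
    labels[order] = np.repeat([1, 2, 3], counts)
    return labels


def simulate_phantom(spec: PhantomSpec) -> tuple[DynamicImage, np.ndarray]:
    """4-D phantom plus voxelwise ground-truth labels.

    Background voxels have a flat TAC at ``background_suv`` (shifted by a
    per-subject offset) plus i.i.d. Gaussian frame noise; lesion voxels
    follow one archetype each, laid out in contiguous angular sectors
    whose sizes realize the lesion's mixture weights exactly.  The label
    volume is 0 for background and 1-3 for the archetypes.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.schedule.n_frames
    curves = make_archetype_curves(spec.archetypes, spec.schedule)
    level = spec.background_suv + rng.normal(0.0, spec.background_subject_sd)
    vol = np.full((*spec.shape, T), level)
    labels = np.zeros(spec.shape, dtype=np.int8)
    for lesion in spec.lesions:
        inside = _ellipsoid_mask(spec.shape, lesion.center, lesion.radii_mm,
                                 spec.voxel_size)
        if not inside.any():
            raise ValidationError("lesion lies outside the grid")
        labels[inside] = _sector_labels(inside, lesion, rng)
        vol[inside] = curves[labels[inside] - 1]
    vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    img = DynamicImage(np.clip(vol, 0.0, None), spec.voxel_size, spec.schedule)
    return img, labels


# ---------------------------------------------------------------------------
# cohort simulation

def _softmax(y: np.ndarray) -> np.ndarray:
    z = np.exp(y - y.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


def simulate_cohort(n_patients: int = 37, idh_fraction: float = 17 / 37,
                    effect: float = 1.0, censoring_rate: float = 0.02,
                    cutoff_benefit_hr: float = 3.0,
                    seed: int = 0) -> CohortTable:
    """Synthetic cohort with IDH1-linked compositions and survival.

    Per patient: IDH1 status is Bernoulli(``idh_fraction``); the centroid
    composition comes from a logistic-normal whose mean shifts toward
    centroid #1 for mutants and toward #2/#3 for wild-type; TBR, TTP and
    slope get IDH1-dependent location shifts matching the direction seen
    clinically (mutants: lower uptake, later peak, flatter/positive
    slope).  PFS and OS are exponential with a hazard divided by
    ``cutoff_benefit_hr`` when pct_c1 > 90; censoring is an independent
    exponential with the given monthly rate (0 disables censoring).

    ``effect`` scales every group difference; 0 gives the global null.
    """
    if n_patients < 2:
        raise ValidationError("need at least 2 patients")
    if not 0 < idh_fraction < 1:
        raise ValidationError("idh_fraction must lie in (0, 1)")
    if censoring_rate < 0:
        raise ValidationError("censoring_rate must be >= 0")
    rng = np.random.default_rng(seed)
    mutant = rng.random(n_patients) < idh_fraction
    sign = np.where(mutant, 1.0, -1.0)

    # logistic-normal composition over (c1, c2, c3); logits relative to c3
    base = np.array([0.8, 0.6, 0.0])
    delta = np.array([1.6, -0.2, 0.0])
    logits = base + effect * sign[:, None] * delta \
        + rng.normal(0.0, 1.5, size=(n_patients, 3)) * np.array([1, 1, 0])
    pct = 100.0 * _softmax(logits)

    tbr_max = np.exp(rng.normal(np.log(2.9) - effect * sign * 0.12, 0.25))
    tbr_mean = np.clip(tbr_max * rng.normal(0.66, 0.06, n_patients), 0.8, None)
    ref_mean = 0.9
    suv_max = tbr_max * ref_mean
    suv_mean = tbr_mean * ref_mean
    ttp_raw = rng.normal(27.0 + effect * sign * 10.0, 12.0, n_patients)
    ttp = np.clip(np.round(ttp_raw / 5.0) * 5.0, 5.0, 45.0)
    slope = rng.normal(-0.2 + effect * sign * 0.33, 0.4, n_patients)

    benefit = pct[:, 0] > 90.0
    hr = np.where(benefit, 1.0 / cutoff_benefit_hr, 1.0)
    lam_pfs = np.log(2.0) / 10.0 * hr      # baseline median PFS 10 months
    lam_os = np.log(2.0) / 25.0 * hr       # baseline median OS 25 months
    pfs_t = rng.exponential(1.0 / lam_pfs)
    os_t = rng.exponential(1.0 / lam_os)
    if censoring_rate > 0:
        cens = rng.exponential(1.0 / censoring_rate, size=n_patients)
    else:
        cens = np.full(n_patients, np.inf)
    pfs_event = pfs_t <= cens
    os_event = os_t <= cens
    pfs = np.minimum(pfs_t, cens)
    osv = np.minimum(os_t, cens)

    import pandas as pd

    df = pd.DataFrame({
        "id": np.arange(1, n_patients + 1),
        "histology": "synthetic glioma",
        "mib1": rng.integers(0, 60, n_patients),
        "idh1": np.where(mutant, "+", "-"),
        "who_grade": rng.choice(["I", "II", "III", "IV"], n_patients),
        "pct_c1": pct[:, 0], "pct_c2": pct[:, 1], "pct_c3": pct[:, 2],
        "suv_max": suv_max, "suv_mean": suv_mean,
        "tbr_max": tbr_max, "tbr_mean": tbr_mean,
        "ttp_min": ttp, "slope_suv_per_h": slope,
        "pfs_months": pfs, "pfs_event": pfs_event,
        "os_months": osv, "os_event": os_event,
    })
    return CohortTable(df)
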