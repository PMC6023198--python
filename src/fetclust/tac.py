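"""Per-voxel time-activity-curve extraction, normalization and clustering.

Every tumor voxel contributes one time-activity curve (TAC): its SUV over
the dynamic frames.  Curves are z-normalized (zero mean, unit SD per
curve) so that only their *shape* matters, then clustered with k-means
under a dynamic-time-warping (DTW) distance, with DTW barycenter
averaging (DBA) as the centroid-update rule.  The number of clusters is
chosen with the elbow method on the sum of squared errors, and with
k = 3 the learned centroids map onto the three canonical glioma TAC
patterns:

* centroid #1 — slowly and steadily increasing uptake,
* centroid #2 — rapid rise followed by a slow decline,
* centroid #3 — rapid rise followed by a rapid washout.

Once centroids are trained (typically once, on voxels pooled across a
training cohort) new voxels are assigned to the *fixed* centroids by
plain Euclidean distance, which is also the distance used for the elbow
SSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _dtw
from .exceptions import NonSegmentableError, ValidationError
from .io import DynamicImage, FrameSchedule
from .segmentation import TumorMask

__all__ = [
    "TACMatrix",
    "CentroidSet",
    "VoxelAssignment",
    "ElbowProfile",
    "extract_tacs",
    "znormalize",
    "dtw_distance",
    "kmeans_dtw",
    "elbow_profile",
    "select_k_elbow",
    "assign_to_centroids",
    "label_centroids",
]

logger = logging.getLogger(__name__)


@dataclass
class TACMatrix:
    """V x T matrix of voxel TACs plus the voxel coordinates of each row."""

    values: np.ndarray
    voxel_coords: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.voxel_coords = np.asarray(self.voxel_coords)
        if self.values.ndim != 2:
            raise ValidationError("TAC matrix must be 2D (voxels x frames)")
        if self.voxel_coords.shape[0] != self.values.shape[0]:
            raise ValidationError("one coordinate triple per TAC row required")
        if self.normalized:
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1)
            if np.abs(mu).max(initial=0) > 1e-6 or np.abs(sd - 1).max(initial=0) > 1e-6:
                raise ValidationError("rows of a normalized TACMatrix must have "
                                      "mean 0 and SD 1")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class CentroidSet:
    """k learned TAC centroids on the z-normalized scale.

    ``semantic_labels`` maps row index -> label number (1, 2, 3) once the
    three-centroid model has been labeled; rows of a labeled set are
    stored in label order (row 0 is centroid #1).
    """

    curves: np.ndarray
    semantic_labels: dict[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.curves = np.ascontiguousarray(self.curves, dtype=np.float64)
        if self.curves.ndim != 2:
            raise ValidationError("centroid curves must form a 2D array")
        if self.semantic_labels is not None:
            vals = sorted(self.semantic_labels.values())
            if sorted(self.semantic_labels) != list(range(self.k)) or \
                    vals != list(range(1, self.k + 1)):
                raise ValidationError("semantic labels must be a bijection "
                                      "row -> {1..k}")

    @property
    def k(self) -> int:
        return self.curves.shape[0]

    @property
    def n_frames(self) -> int:
        return self.curves.shape[1]


@dataclass
class VoxelAssignment:
    """Winning centroid per voxel plus the distance to it."""

    labels: np.ndarray   # values in 1..k (semantic numbering when available)
    distances: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.labels.shape != self.distances.shape:
            raise ValidationError("labels and distances must align")
        if self.labels.size and self.labels.min() < 1:
            raise ValidationError("labels are 1-based")
        if np.any(self.distances < 0):
            raise ValidationError("distances must be non-negative")


@dataclass
class ElbowProfile:
    """SSE as a function of the number of clusters k."""

    k_values: list[int]
    sse: list[float]

    def __post_init__(self):
        if len(self.k_values) != len(self.sse):
            raise ValidationError("k_values and sse must align")
        if any(s < 0 for s in self.sse):
            raise ValidationError("SSE must be non-negative")


# ---------------------------------------------------------------------------
# extraction and normalization

def extract_tacs(img: DynamicImage, mask: TumorMask) -> TACMatrix:
    """One raw-SUV TAC per foreground voxel of the tumor mask."""
    if mask.voxels.shape != img.shape:
        raise ValidationError(
            f"mask shape {mask.voxels.shape} does not match image {img.shape}")
    if mask.is_empty:
        raise NonSegmentableError("tumor mask is empty (non-segmentable scan)")
    coords = np.argwhere(mask.voxels)
    values = img.voxels[mask.voxels]
    return TACMatrix(values, coords, normalized=False)


def znormalize(tacs: TACMatrix) -> TACMatrix:
    """Rowwise z-normalization: T -> (T - mean(T)) / std(T).

    The SD is the population SD (denominator n).  Rows with zero variance
    carry no shape information and cannot be normalized; they are dropped
    and their count logged.
    """
    if tacs.normalized:
        raise ValidationError("TACMatrix is already normalized")
    sd = tacs.values.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("znormalize: dropped %d zero-variance TAC(s)", n_dropped)
    if not keep.any():
        raise ValidationError("all TACs have zero variance")
    vals = tacs.values[keep]
    out = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep, None]
    return TACMatrix(out, tacs.voxel_coords[keep], normalized=True)


# ---------------------------------------------------------------------------
# DTW distance

def dtw_distance(Q, C, local_cost: str = "absolute") -> float:
    """Dynamic-time-warping distance between two series.

    Unconstrained DP over the recurrence
    ``gamma(i,j) = d(q_i, c_j) + min(diag, up, left)``; ``local_cost`` is
    ``"absolute"`` (|q-c|, the default) or ``"squared"``.
    """
    Q = np.ascontiguousarray(Q, dtype=np.float64)
    C = np.ascontiguousarray(C, dtype=np.float64)
    if Q.ndim != 1 or C.ndim != 1 or Q.size == 0 or C.size == 0:
        raise ValidationError("dtw_distance expects two non-empty 1D series")
    return float(_dtw.dtw_cost(Q, C, _squared_flag(local_cost)))


def _squared_flag(local_cost: str) -> bool:
    if local_cost not in ("absolute", "squared"):
        raise ValidationError(f"unknown local cost {local_cost!r}")
    return local_cost == "squared"


def _renorm_rows(curves: np.ndarray) -> np.ndarray:
    """Project centroid curves back onto the z-normalized scale."""
    mu = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (curves - mu) / sd


# ---------------------------------------------------------------------------
# k-means over DTW

def kmeans_dtw(tacs: TACMatrix, k: int, seed: int, n_init: int = 10,
               max_iter: int = 50, local_cost: str = "absolute",
               dba_iter: int = 10,
               ) -> tuple[CentroidSet, VoxelAssignment, float]:
    """Lloyd-style k-means with DTW assignment and DBA centroid updates.

    Each of ``n_init`` restarts initializes centroids on ``k`` distinct
    randomly chosen curves, alternates DTW nearest-centroid assignment
    with a DBA update (at most ``dba_iter`` inner passes), and stops when
    the assignment no longer changes.  After every update, centroids are
    re-projected onto the z-normalized scale so they stay comparable with
    the curves they summarize.  The restart with the lowest inertia (sum
    of squared DTW distances) wins.  Deterministic given ``seed``.
    """
    if not tacs.normalized:
        raise ValidationError("kmeans_dtw requires z-normalized TACs")
    X = tacs.values
    V = X.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if V < k:
        raise ValidationError(f"cannot form {k} clusters from {V} curves")
    squared = _squared_flag(local_cost)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centroids = X[rng.choice(V, size=k, replace=False)].copy()
        labels = np.full(V, -1, dtype=np.int64)
        for _ in range(max_iter):
            new_labels, dists = _dtw.dtw_assign(X, centroids, squared)
            # re-seed empty clusters on the worst-fitted curve
            for ci in range(k):
                if not np.any(new_labels == ci):
                    far = int(np.argmax(dists))
                    centroids[ci] = X[far]
                    new_labels[far] = ci
                    dists[far] = 0.0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centroids = _renorm_rows(
                _dtw.dba_update(X, labels, centroids, dba_iter, squared, 1e-6))
        labels, dists = _dtw.dtw_assign(X, centroids, squared)
        inertia = float(np.sum(dists ** 2))
        if best is None or inertia < best[2]:
            best = (centroids.copy(), labels.copy(), inertia)
    centroids, labels, inertia = best
    cs = CentroidSet(centroids, metadata={
        "k": k, "seed": int(seed), "n_init": int(n_init),
        "inertia": inertia, "local_cost": local_cost})
    assign = VoxelAssignment(labels + 1, np.asarray(
        _dtw.dtw_assign(X, centroids, squared)[1]))
    return cs, assign, inertia


# ---------------------------------------------------------------------------
# elbow model selection

def elbow_profile(tacs: TACMatrix, k_max: int = 8, seed: int = 0,
                  n_init: int = 10, **kmeans_kwargs) -> ElbowProfile:
    """SSE(k) for k = 1..k_max.

    For each k the centroids come from :func:`kmeans_dtw` (best of
    ``n_init`` restarts); the SSE sums, over curves, the squared
    *Euclidean* distance to the nearest centroid — the same distance used
    for the final voxel-assignment rule.
    """
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    ks, sses = [], []
    for k in range(1, k_max + 1):
        cs, _, _ = kmeans_dtw(tacs, k, seed=seed, n_init=n_init, **kmeans_kwargs)
        d2 = ((tacs.values[:, None, :] - cs.curves[None, :, :]) ** 2).sum(axis=2)
        sses.append(float(d2.min(axis=1).sum()))
        ks.append(k)
    return ElbowProfile(ks, sses)


def select_k_elbow(profile: ElbowProfile) -> int:
    """Pick k at the elbow: the largest relative SSE drop.

    The selected k is the one ending the drop
    ``(SSE(k-1) - SSE(k)) / SSE(k-1)`` that is largest; ties go to the
    smaller k.  Past the elbow, extra clusters buy only marginal SSE.
    """
    sse = np.asarray(profile.sse, float)
    if sse.size < 2:
        raise ValidationError("need SSE for at least two k values")
    prev = sse[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(prev > 0, (prev - sse[1:]) / prev, 0.0)
    return int(profile.k_values[int(np.argmax(rel)) + 1])


# ---------------------------------------------------------------------------
# assignment to frozen centroids and semantic labeling

def assign_to_centroids(tacs: TACMatrix, centroids: CentroidSet) -> VoxelAssignment:
    """Assign each curve to the closest centroid by Euclidean distance.

    This is the final classification rule for frozen centroids (training
    uses DTW; assignment does not).  Ties go to the lowest label.
    """
    if not tacs.normalized:
        raise ValidationError("assignment requires z-normalized TACs")
    if tacs.n_frames != centroids.n_frames:
        raise ValidationError(
            f"TAC length {tacs.n_frames} != centroid length {centroids.n_frames}")
    d2 = ((tacs.values[:, None, :] - centroids.curves[None, :, :]) ** 2).sum(axis=2)
    winner = d2.argmin(axis=1)  # argmin takes the first (lowest) on ties
    dist = np.sqrt(d2[np.arange(tacs.n_voxels), winner])
    if centroids.semantic_labels is not None:
        labels = np.array([centroids.semantic_labels[w] for w in winner])
    else:
        labels = winner + 1
    return VoxelAssignment(labels, dist)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def label_centroids(centroids: CentroidSet, schedule: FrameSchedule,
                    late_window: tuple[float, float] = (20.0, 50.0),
                    early_window: tuple[float, float] = (0.0, 15.0),
                    ) -> CentroidSet:
    """Attach the canonical #1/#2/#3 labels to a 3-centroid model.

    Labels are ordered by the late-phase (20-50 min) OLS slope of each
    curve: #1 is the most positive (slow accumulation), #3 the most
    negative (rapid washout), #2 the remaining pattern.  Exact late-slope
    ties are broken by the early (0-15 min) slope, the flatter early rise
    winning #1.  The returned set has its rows reordered so row i holds
    centroid #(i+1).
    """
    if centroids.k != 3:
        raise ValidationError("semantic labels are defined for k=3 only")
    if centroids.n_frames != schedule.n_frames:
        raise ValidationError("centroid length does not match schedule")
    idx = schedule.frames_in_window(late_window)
    if idx.size < 2:
        raise ValidationError("late window covers fewer than 2 frames")
    t_late = schedule.mid_times[idx]
    late = np.array([_ols_slope(t_late, c[idx]) for c in centroids.curves])
    eidx = schedule.frames_in_window(early_window)
    early = np.array([_ols_slope(schedule.mid_times[eidx], c[eidx])
                      for c in centroids.curves]) if eidx.size >= 2 else np.zeros(3)
    # quantize so numerically indistinguishable late slopes count as tied
    late_key = np.round(late, 9)
    if len(np.unique(late_key)) < 3:
        logger.info("label_centroids: late-slope tie broken by early slope")
    # most positive late slope first; flatter early rise wins on ties
    order = np.lexsort((early, -late_key))
    curves = centroids.curves[order]
    meta = dict(centroids.metadata)
    meta["late_slopes_per_hour"] = (late[order] * 60.0).tolist()
    return CentroidSet(curves, semantic_labels={0: 1, 1: 2, 2: 3}, metadata=meta)
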