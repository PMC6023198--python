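"""End-to-end pipeline orchestration.

``run_pipeline`` drives template -> segmentation -> TAC clustering ->
features -> cohort stats over a manifest of patients, writing every
artifact (masks, centroids, features.csv, report.json, run log) into an
output directory.  Scans whose Z-score map yields no admissible cluster
are recorded as non-segmentable and excluded from the feature table,
the same way visually normal scans drop out of a clinical cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .exceptions import FetclustError, ValidationError
from .features import build_feature_record, mirror_reference_mask
from .segmentation import (build_template, make_tumor_mask, smooth_gaussian,
                           static_from_dynamic, zscore_map)
from .tac import (assign_to_centroids, extract_tacs, kmeans_dtw,
                  label_centroids, znormalize)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables, defaulting to the published protocol."""

    z_threshold: float = 2.5
    min_cluster_voxels: int = 250
    dilation_iterations: int = 2
    connectivity: int = 2
    fwhm_mm: float = 8.0
    smooth_dynamic_frames: bool = True
    k: int = 3
    k_max: int = 8
    n_init: int = 10
    seed: int = 17
    static_window: tuple[float, float] = (40.0, 50.0)
    slope_window: tuple[float, float] = (20.0, 50.0)
    cutpoint_min_group_frac: float = 0.1

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_patient(entry: dict) -> fio.DynamicImage:
    return fio.read_dynamic(entry["pet"], entry["timing"])


def run_pipeline(config: PipelineConfig, manifest: list[dict], outdir,
                 template=None, centroids=None) -> Path:
    """Run the full analysis over a patient manifest.

    Each manifest entry is a dict with ``id``, ``pet`` (4-D NIfTI path),
    ``timing`` (sidecar path) and optionally ``ref`` (reference-region
    mask path) plus passthrough fields (``idh1`` ...).  ``template`` is a
    :class:`~fetclust.segmentation.NormalTemplate`; when ``centroids``
    is None a 3-centroid model is trained on the pooled tumor voxels of
    all segmentable patients, then frozen for assignment.

    Per-patient failures are recorded and the run continues.  Returns
    the output directory, containing per-patient masks, centroids.json,
    features.csv and run.json.
    """
    if template is None:
        raise ValidationError("a normal template is required (build one "
                              "with build_template)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config": dataclasses.asdict(config),
                     "config_hash": config.config_hash(),
                     "patients": {}, "non_segmentable": [], "errors": {}}

    staged = []  # (entry, img, mask, normalized TACs)
    for entry in manifest:
        pid = str(entry["id"])
        try:
            img = _load_patient(entry)
            if config.smooth_dynamic_frames:
                sm = np.stack([smooth_gaussian(img.voxels[..., t],
                                               config.fwhm_mm, img.voxel_size)
                               for t in range(img.schedule.n_frames)], axis=-1)
                img = fio.DynamicImage(np.clip(sm, 0, None), img.voxel_size,
                                       img.schedule, affine=img.affine)
            static = static_from_dynamic(img, config.static_window)
            if not config.smooth_dynamic_frames:
                static.voxels = smooth_gaussian(static.voxels, config.fwhm_mm,
                                                img.voxel_size)
            z = zscore_map(static, template)
            mask = make_tumor_mask(
                z, z_threshold=config.z_threshold,
                min_cluster_voxels=config.min_cluster_voxels,
                dilation_iterations=config.dilation_iterations,
                connectivity=config.connectivity,
                voxel_size=img.voxel_size, affine=img.affine)
            fio.write_mask(mask, outdir / f"{pid}_mask.nii.gz")
            if mask.non_segmentable:
                run_log["non_segmentable"].append(pid)
                logger.warning("patient %s: non-segmentable scan", pid)
                continue
            tacs = znormalize(extract_tacs(img, mask))
            staged.append((entry, img, mask, tacs))
        except FetclustError as exc:
            run_log["errors"][pid] = str(exc)
            logger.error("patient %s failed: %s", pid, exc)

    if centroids is None:
        if not staged:
            raise ValidationError("no segmentable patients to train on")
        from .tac import TACMatrix
        pooled = TACMatrix(
            np.vstack([t.values for *_, t in staged]),
            np.vstack([t.voxel_coords for *_, t in staged]),
            normalized=True)
        cs, _, _ = kmeans_dtw(pooled, config.k, seed=config.seed,
                              n_init=config.n_init)
        centroids = label_centroids(cs, staged[0][1].schedule)
    fio.write_centroids(centroids, outdir / "centroids.json")

    rows = []
    for entry, img, mask, tacs in staged:
        pid = str(entry["id"])
        try:
            assign = assign_to_centroids(tacs, centroids)
            ref = (fio.read_mask(entry["ref"]) if entry.get("ref")
                   else mirror_reference_mask(mask))
            rec = build_feature_record(
                pid, assign, img, mask, ref_mask=ref,
                static_window=config.static_window,
                slope_window=config.slope_window)
            row = rec.as_dict()
            for key in ("idh1", "pfs_months", "pfs_event",
                        "os_months", "os_event"):
                if key in entry:
                    row[key] = entry[key]
            rows.append(row)
            run_log["patients"][pid] = {"n_tumor_voxels": mask.n_voxels,
                                        "volume_ml": mask.volume_ml()}
        except FetclustError as exc:
            run_log["errors"][pid] = str(exc)
            logger.error("patient %s failed: %s", pid, exc)

    if rows:
        pd.DataFrame(rows).to_csv(outdir / "features.csv", index=False)
    with open(outdir / "run.json", "w") as fh:
        json.dump(run_log, fh, indent=1, default=str)
    return outdir
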