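# Methods

This note documents the models, conventions and numerical choices behind
`fetclust`, and what the synthetic test bed does and does not establish.

## Data model

A dynamic scan is a 4-D SUV volume with a frame schedule (start time and
duration per frame, minutes post-injection; default 10 × 5 min spanning
0–50 min). Frame timing travels in a BIDS-like JSON sidecar
(`FrameTimesStart` / `FrameDuration`) because the NIfTI header has no
standard slot for it. All volumes entering the pipeline are assumed to
share one voxel grid: spatial realignment and template registration are
upstream preprocessing, out of scope here.

## Segmentation

* **Static image**: the voxelwise *mean* SUV over frames starting in
  [40, 50) min. The mean (not the literal sum) keeps the image in SUV;
  Z-scores and uptake ratios are invariant to this scale choice.
* **Template**: voxelwise mean and sample SD (ddof = 1) over ≥ 2 normal
  static scans. Before use, the SD is floored at the 5th percentile of
  its nonzero values so that near-constant regions cannot blow up the
  Z-map; the floor is configurable.
* **Z-map**: Z = (patient − mean)/max(SD, floor). The "Z-score"
  nomenclature implies SD normalization even where a plain difference
  could be meant; the normalized form is used throughout.
* **Mask**: threshold Z > 2.5, label connected components
  (18-connectivity by default, configurable — the usual convention in
  SPM-style neuroimaging), keep components of ≥ 250 voxels, then dilate
  the union with the 6-connected 3×3×3 cross, 2 iterations. An empty
  result is legal and flagged *non-segmentable* rather than raising; in
  a clinical cohort these are the visually normal scans that drop out.
* **Smoothing**: 8-mm FWHM Gaussian (σ = FWHM/(2√(2 ln 2)) per axis in
  voxel units). By default every dynamic frame is smoothed before TAC
  extraction as well as the static image before Z-mapping; a config
  flag restricts smoothing to the static image only, since protocols
  differ on this point.

**Accuracy expectations.** The dilation step is deliberately
over-inclusive — it exists to catch adjacent borderline voxels — so
delineation accuracy should be judged on the *pre-dilation* mask. On the
default phantom (~24 mL lesion, ≥ 4 SD contrast) the pre-dilation Dice
against ground truth exceeds 0.7 and the dilated mask covers ≥ 95 % of
the true lesion. Two dilation iterations inflate a small lesion's
volume substantially (a 2 mL sphere by ~3.4×), which geometrically caps
the post-dilation Dice near 0.45 regardless of delineation quality;
post-dilation Dice is therefore not a meaningful quality metric for
small lesions.

## TAC clustering

* **Normalization**: per curve, T → (T − mean T)/std T with the
  population SD (denominator n). Zero-variance curves carry no shape
  information, cannot be normalized, and are dropped with a logged
  count.
* **DTW**: unconstrained dynamic programming over
  γ(i,j) = d(qᵢ,cⱼ) + min(γ(i−1,j−1), γ(i−1,j), γ(i,j−1)), boundary
  γ(1,1) = d(q₁,c₁), no warping window. The local cost is |qᵢ−cⱼ| by
  default ("Euclidean distance" between scalars); a squared-cost
  variant is available. Kernels are numba-jitted; the test suite
  cross-checks them against an independent memoized-recursion oracle to
  1e-9.
* **k-means**: Lloyd iterations with DTW assignment and DTW barycenter
  averaging (DBA, ≤ 10 inner passes) as the centroid update; after each
  update centroids are re-projected to zero mean/unit SD so they stay
  on the scale of the curves they summarize. 10 random restarts
  (centroids seeded on k distinct curves), best restart by inertia
  (sum of squared DTW distances); empty clusters are re-seeded on the
  worst-fitted curve. Fully deterministic given the seed.
* **Model selection**: SSE(k) for k = 1..8, where SSE is the squared
  *Euclidean* distance of each curve to its nearest centroid — the same
  distance as the final assignment rule. The elbow picks the k ending
  the largest relative drop (SSE(k−1) − SSE(k))/SSE(k−1), ties to the
  smaller k. Because training (DTW/DBA) and evaluation (Euclidean)
  distances differ, SSE(k) is guaranteed to decrease only while real
  cluster structure is being absorbed; past it (k ≳ 4 on
  three-archetype data) SSE can tick up by a few percent. The elbow
  decision only depends on the large early drops and is unaffected.
* **Assignment and labels**: voxels are classified to frozen centroids
  by plain Euclidean distance (training uses DTW; final assignment does
  not — the two roles are deliberately kept distinct). Ties go to the
  lowest label. For k = 3 the centroids are ordered by late-phase
  (20–50 min) OLS slope: most positive → #1, most negative → #3. Late
  slopes are quantized at 1e-9 before ordering so numerically
  indistinguishable slopes count as tied; exact ties are broken by the
  early (0–15 min) slope, the flatter early rise winning #1.
* **Training population**: centroids are meant to be learned once on
  voxels pooled across a training cohort and then frozen; the pipeline
  trains on the pooled voxels of all segmentable patients in a run when
  no centroid file is supplied.

## Features

* **TTP** is the *start time* of the frame holding the maximum of the
  tumor mean TAC (first frame on ties), giving the value set
  {0, 5, …, 45} on the default protocol. (Mid- or end-time conventions
  would give 2.5–47.5 or 5–50 and do not match the observed value set.)
  A TTP of 0 (monotonically decreasing TAC) is possible in principle
  and flagged by its being below the smallest clinically observed
  value.
* **Late slope**: OLS of the tumor mean TAC against frame mid-times
  over [20, 50) min, expressed in SUV/hour. With uniform frame spacing
  the slope is identical for start or mid times.
* **SUVmax/SUVmean** are computed on the 40–50 min static image
  (clinical convention); a config flag switches to the dynamic maximum.
* **TBR**: tumor SUVmax and SUVmean divided by the mean SUV of a
  reference region in contralateral normal brain. The clinical
  reference is an operator-drawn crescent in the centrum semiovale;
  since its geometry is operator-dependent, the package accepts a
  user-supplied mask and otherwise falls back to mirroring the tumor
  bounding box across the mid-sagittal plane (eroded, tumor-excluded).
  The fallback is only validated on phantoms.
* Centroid percentages sum to 100 exactly before rounding; records
  accept 100 ± 0.1 to absorb printed rounding.

## Cohort statistics

* **Mann-Whitney U**: U from midranks; exact p for tie-free samples
  with both n ≤ 8, otherwise the tie-corrected normal approximation
  without continuity correction.
* **Chi-square**: Pearson on 2×2 tables, df = 1, no Yates correction.
* **Survival**: Kaplan-Meier product-limit curves (lifelines) and the
  two-group log-rank test; both are cross-checked against hand
  product-limit and O−E computations in the tests.
* **Optimal cutpoint**: exhaustive scan of midpoints between
  consecutive unique values, keeping thresholds that leave at least a
  configurable fraction (default 10 %) of subjects on each side, and
  returning the threshold maximizing the log-rank χ². The p-value is
  reported *uncorrected* and flagged as such: maximizing over
  thresholds inflates type-I error, and any threshold found this way is
  exploratory. Simulation shows the scan is noisy at n = 37: with a
  true hazard ratio of 3 above pct_c1 = 90, the recovered threshold
  falls within ±5 of the truth in only ~44 % of replicates (median
  absolute offset ~6) — far above the ~12 % chance rate, but not a
  precise estimate. Quartiles use the inclusive (Tukey hinge)
  convention. One known discrepancy in the bundled reference cohort:
  the published summary's TBRmax median (2.9) cannot be recovered from
  the rounded per-patient values, which give 3.1 under any standard
  convention; TTP, slope and TBRmean medians do recover.

## Synthetic data

* **Archetypes** are piecewise-linear curves through (first mid-time,
  start), (peak time, peak) and (last mid-time, end), with defaults
  chosen to produce the three canonical shapes over a ~1 SUV brain
  background: slow riser (peak at the end, late slope > 0), moderate
  riser with slow decline, fast riser with rapid washout. Construction
  validates the taxonomy (late slopes s₁ > 0 and s₃ < s₂ < 0, all
  values ≥ 0).
* **Voxel TACs**: archetype curve + i.i.d. Gaussian noise (default SD
  0.2 SUV), clipped at 0.
* **Phantoms**: a 60×48×48 grid of 2-mm voxels; background is a flat
  TAC at 1 SUV with a per-subject level shift (SD 0.15, a realistic
  between-subject spread for normalized uptake) plus frame noise; one
  lateralized ellipsoidal lesion of ~24 mL by default (typical glioma
  scale, and large enough that dilation does not dominate the mask).
  Lesion voxels follow one archetype each, laid out in contiguous
  angular wedges whose sizes realize the mixture weights exactly —
  kinetic subregions in real tumors are spatially coherent, and an
  i.i.d. per-voxel mixture would be homogenized by the 8-mm smoothing
  step.
* **Cohorts**: IDH1 status ~ Bernoulli; centroid compositions from a
  logistic-normal on the 3-simplex (guaranteeing the sum-to-100
  constraint) whose mean shifts toward centroid #1 for mutants;
  TBR/TTP/slope with IDH1-dependent location shifts matching the
  clinically observed directions; PFS/OS exponential with the hazard
  divided by 3 when pct_c1 > 90; independent exponential censoring. A
  single `effect` scalar scales all group differences (0 = global
  null), which is what the type-I-error and power tests exercise.
* Everything is bit-reproducible given the seed.

**What the phantoms do not show.** No PET physics (attenuation,
scatter, partial volume, reconstruction texture, frame-dependent count
statistics), no anatomy, no registration error, sharp lesion borders,
and Gaussian noise that is white in space and time. Passing tests
establish that the algorithms recover known structure under the stated
noise model — not scanner-level performance on patient data.

## Problem sizes and determinism

Test and acceptance runs use 300-curve clustering problems (100 per
archetype), 2 000 curves for proportion recovery, 41 simulated normals
for the template, 20 replicates for elbow stability and 40–400
replicates for the statistical calibration checks — sizes at which the
behavior of interest is already stable and a full run stays fast on one
CPU. All stochastic steps take explicit seeds; k-means restarts derive
from one generator, so a fixed seed reproduces centroids, assignments
and inertia bit-for-bit.

## Known limitations

* Spatial preprocessing (realignment, MNI normalization) is assumed
  done; the package does not register images.
* The mirrored-bounding-box reference region is a phantom-validated
  fallback, not a substitute for a curated contralateral ROI.
* Semantic labels #1/#2/#3 are defined only for the k = 3 model.
* DBA centroids depend on initialization; with 10 restarts the
  three-archetype problem converges to the same solution across seeds,
  but heavily overlapping clusters may not.
* The cutpoint scan's threshold estimate is exploratory at cohort sizes
  around 37 (see above) and its p-value is uncorrected by design.
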