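# fetclust

Voxel-wise time-activity-curve (TAC) clustering for dynamic
¹⁸F-fluoro-ethyl-tyrosine (FET) PET of gliomas.

## The problem

Amino-acid PET tracers such as ¹⁸F-FET depict gliomas with high
tumor-to-background contrast, and the *shape* of the uptake curve over a
40–50 min dynamic acquisition carries diagnostic and prognostic
information: steadily accumulating tumors behave differently from tumors
with rapid uptake and washout. Conventional analyses reduce the whole
tumor to a single region-level curve; `fetclust` instead classifies
**every tumor voxel** into one of three canonical kinetic patterns and
uses the resulting composition as a per-patient imaging feature:

* **centroid #1** — slowly increasing uptake,
* **centroid #2** — rapid rise followed by a slow decline,
* **centroid #3** — rapid rise followed by a rapid washout.

The package is aimed at nuclear-medicine researchers who want a fully
automatic, reproducible pipeline from a 4-D SUV volume to cohort-level
statistics (IDH1 association, survival stratification).

## Method

1. **Segmentation.** A late static image (mean SUV over 40–50 min,
   smoothed with an 8-mm FWHM Gaussian) is compared voxelwise against a
   normal-brain template (mean μ and SD σ over visually normal scans):
   Z = (patient − μ)/σ. Voxels with Z > 2.5 are grouped into connected
   components; components with ≥ 250 voxels are kept and dilated twice
   with a 6-connected 3×3×3 cross. Scans with no admissible component
   are flagged *non-segmentable* and excluded.
2. **TAC clustering.** Each tumor voxel's 10-frame TAC T is
   z-normalized, T → (T − mean T)/std T, and clustered with k-means
   under the dynamic-time-warping distance
   γ(i,j) = d(qᵢ,cⱼ) + min(γ(i−1,j−1), γ(i−1,j), γ(i,j−1)),
   with DTW barycenter averaging as the centroid update. The number of
   clusters is chosen by the elbow of the SSE(k) curve, k = 1..8; with
   the three archetypes above the elbow sits at k = 3. Frozen centroids
   are labeled #1/#2/#3 by their late-phase (20–50 min) slope, and new
   voxels are assigned to the nearest centroid by plain Euclidean
   distance.
3. **Features.** Per patient: centroid percentages (pct_c1/c2/c3),
   SUVmax/SUVmean on the late static image, TBRmax/TBRmean against a
   contralateral reference region, time-to-peak (start time of the
   maximum frame of the tumor mean TAC, minutes) and late slope (OLS
   over 20–50 min, SUV/hour).
4. **Cohort statistics.** Mann-Whitney U and Pearson chi-square group
   comparisons, Kaplan-Meier estimates with log-rank tests, and an
   exhaustive optimal-cutpoint scan (maximally selected log-rank
   statistic, reported with an explicit *uncorrected-p* flag).

A synthetic module generates 4-D phantoms and cohorts with known ground
truth so the full pipeline is testable without patient data.

## Worked example

Cluster 300 synthetic voxel TACs (100 per archetype, noise SD 0.2):

```python
import numpy as np
from fetclust.io import FrameSchedule
from fetclust.synthetic import simulate_tacs
from fetclust.tac import (TACMatrix, znormalize, elbow_profile, select_k_elbow,
                          kmeans_dtw, label_centroids, assign_to_centroids)
from fetclust.features import centroid_proportions

X, truth = simulate_tacs(n_per_archetype=100, noise_sd=0.2, seed=7)
tacs = znormalize(TACMatrix(X, np.zeros((300, 3), int)))

profile = elbow_profile(tacs, k_max=8, seed=7)
print("SSE(k):", [round(s) for s in profile.sse])
print("elbow-selected k:", select_k_elbow(profile))

centroids, _, inertia = kmeans_dtw(tacs, k=3, seed=7)
centroids = label_centroids(centroids, FrameSchedule.default())
assignment = assign_to_centroids(tacs, centroids)
print("centroid proportions (%):",
      [round(p, 1) for p in centroid_proportions(assignment)])
print("accuracy vs ground truth:", round((assignment.labels == truth).mean(), 3))
```

prints

```
SSE(k): [2163, 1197, 351, 324, 313, 307, 291, 290]
elbow-selected k: 3
centroid proportions (%): [33.3, 33.3, 33.3]
accuracy vs ground truth: 1.0
```

The SSE drops abruptly until k = 3 and flattens after — the elbow — and
the recovered composition matches the generating mixture exactly.

On the bundled reference cohort of 37 glioma patients:

```python
from fetclust import load_reference_cohort
from fetclust.stats import summarize_by_mutation, chi_square_2x2

cohort = load_reference_cohort()
print(summarize_by_mutation(cohort)[["median_all", "median_wt",
                                     "median_mut", "p_mann_whitney"]].round(3))
```

```
                 median_all  median_wt  median_mut  p_mann_whitney
variable
tbr_max                3.10      3.350        2.80           0.035
tbr_mean               2.10      2.400        2.00           0.016
ttp_min               25.00     17.500       40.00           0.027
slope_suv_per_h       -0.08     -0.555        0.13           0.021
```

IDH1-mutant tumors peak later (median TTP 40 vs 17.5 min) with a flat or
positive late slope — the kinetic signature that centroid #1 captures at
the voxel level. Splitting the cohort at pct_c1 > 90 % gives 10/13
mutants above versus 7/24 below (χ² = 7.74, p = 0.0054).

The `fetclust` console script exposes the same steps as subcommands
(`simulate`, `build-template`, `segment`, `train`, `elbow`, `features`,
`stats`, `run`); see `fetclust --help`.

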