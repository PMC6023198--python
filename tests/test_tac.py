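import functools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fetclust.exceptions import NonSegmentableError, ValidationError
from fetclust.io import DynamicImage, FrameSchedule
from fetclust.segmentation import TumorMask
from fetclust.synthetic import simulate_tacs
from fetclust.tac import (CentroidSet, TACMatrix, assign_to_centroids,
                          dtw_distance, elbow_profile, extract_tacs,
                          kmeans_dtw, label_centroids, select_k_elbow,
                          znormalize)


def dtw_brute_force(q, c):
    """Independent oracle: memoized recursion over the warping recurrence."""
    q = tuple(float(x) for x in q)
    c = tuple(float(x) for x in c)

    @functools.lru_cache(maxsize=None)
    def gamma(i, j):
        d = abs(q[i] - c[j])
        if i == 0 and j == 0:
            return d
        preds = []
        if i > 0 and j > 0:
            preds.append(gamma(i - 1, j - 1))
        if i > 0:
            preds.append(gamma(i - 1, j))
        if j > 0:
            preds.append(gamma(i, j - 1))
        return d + min(preds)

    return gamma(len(q) - 1, len(c) - 1)


def _mat(X):
    return TACMatrix(np.asarray(X, float), np.zeros((len(X), 3), int))


series = st.lists(st.floats(-5, 5, allow_nan=False, width=32),
                  min_size=2, max_size=12)


class TestExtractTacs:
    def test_shape_matches_mask(self, schedule):
        vol = np.random.default_rng(0).random((4, 4, 4, 10)) + 0.1
        img = DynamicImage(vol, (2, 2, 2), schedule)
        mask = np.zeros((4, 4, 4), bool)
        mask[[0, 1, 2], [0, 1, 2], [0, 1, 2]] = True
        tacs = extract_tacs(img, TumorMask(mask))
        assert tacs.values.shape == (3, 10)
        assert not tacs.normalized
        np.testing.assert_allclose(tacs.values[0], vol[0, 0, 0])

    def test_empty_mask_is_non_segmentable(self, schedule):
        img = DynamicImage(np.ones((3, 3, 3, 10)), (2, 2, 2), schedule)
        with pytest.raises(NonSegmentableError):
            extract_tacs(img, TumorMask(np.zeros((3, 3, 3), bool)))


class TestZNormalize:
    def test_hand_example(self):
        out = znormalize(_mat([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values[0], [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_zero_variance_rows_dropped(self):
        out = znormalize(_mat([[1.0, 2.0, 3.0], [5.0] * 3]))
        assert out.n_voxels == 1

    def test_all_constant_rejected(self):
        with pytest.raises(ValidationError):
            znormalize(_mat([[2.0, 2.0, 2.0]]))

    def test_renormalizing_normalized_shape_is_identity(self):
        first = znormalize(_mat([[0.5, 1.5, 4.0, 2.0]]))
        again = (first.values - first.values.mean(axis=1, keepdims=True)) \
            / first.values.std(axis=1, keepdims=True)
        np.testing.assert_allclose(again, first.values, atol=1e-12)

    @given(st.lists(series.filter(lambda r: max(r) - min(r) > 1e-3),
                    min_size=1, max_size=6).map(
        lambda rows: [r[: len(rows[0])] for r in rows]).filter(
        lambda rows: min(len(r) for r in rows) == len(rows[0])))
    def test_rows_have_zero_mean_unit_sd(self, rows):
        out = znormalize(_mat(rows))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-9)


class TestDTWDistance:
    def test_identity_is_zero(self):
        x = np.array([0.3, 1.2, -0.7, 2.0])
        assert dtw_distance(x, x) == 0.0

    def test_warping_absorbs_shift(self):
        # hand-computed full gamma matrix gives 0
        assert dtw_distance([0, 1, 1], [0, 0, 1]) == 0.0

    def test_no_alignment_possible(self):
        # gamma(2,2) = 1 + min(1, 2, 2) = 2
        assert dtw_distance([0, 0], [1, 1]) == 2.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            dtw_distance([], [1.0])

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            q = rng.normal(size=10)
            c = rng.normal(size=10)
            assert dtw_distance(q, c) == pytest.approx(
                dtw_brute_force(q, c), abs=1e-9)

    @given(series, series)
    def test_symmetry_and_diagonal_bound(self, q, c):
        d_qc = dtw_distance(q, c)
        assert d_qc == pytest.approx(dtw_distance(c, q), abs=1e-9)
        assert d_qc >= 0
        if len(q) == len(c):
            diagonal = float(np.abs(np.asarray(q) - np.asarray(c)).sum())
            assert d_qc <= diagonal + 1e-9


class TestKMeansDTW:
    def test_identical_points_single_cluster(self):
        X = np.tile([0.0, 1.0, -1.0, 0.0], (5, 1))
        X = znormalize(_mat(X + np.arange(4) * 0.0))  # still identical rows
        cs, assign, inertia = kmeans_dtw(X, 1, seed=0, n_init=2)
        assert inertia == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(cs.curves[0], X.values[0], atol=1e-9)

    def test_k_equals_v_zero_inertia(self):
        X, _ = simulate_tacs(2, noise_sd=0.3, seed=5)  # 6 distinct curves
        mat = znormalize(_mat(X))
        _, _, inertia = kmeans_dtw(mat, mat.n_voxels, seed=0, n_init=3)
        assert inertia == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        mat = znormalize(_mat([[0, 1, 2.0], [2, 1, 0.0]]))
        with pytest.raises(ValidationError):
            kmeans_dtw(mat, 3, seed=0)

    def test_recovers_archetype_partition(self):
        X, truth = simulate_tacs(100, noise_sd=0.2, seed=21)
        mat = znormalize(_mat(X))
        _, assign, _ = kmeans_dtw(mat, 3, seed=4)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, assign.labels) >= 0.9

    def test_same_seed_reproducible(self):
        X, _ = simulate_tacs(30, noise_sd=0.2, seed=9)
        mat = znormalize(_mat(X))
        a = kmeans_dtw(mat, 3, seed=11, n_init=4)
        b = kmeans_dtw(mat, 3, seed=11, n_init=4)
        np.testing.assert_array_equal(a[0].curves, b[0].curves)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)
        assert a[2] == b[2]


class TestElbow:
    def test_three_archetypes_select_k3(self):
        X, _ = simulate_tacs(100, noise_sd=0.2, seed=31)
        mat = znormalize(_mat(X))
        prof = elbow_profile(mat, k_max=8, seed=2)
        assert select_k_elbow(prof) == 3

    def test_single_archetype_has_no_late_elbow(self):
        X, _ = simulate_tacs(weights=(1, 0, 0), n_total=150, noise_sd=0.2,
                             seed=13)
        mat = znormalize(_mat(X))
        prof = elbow_profile(mat, k_max=4, seed=2)
        # homogeneous data: splitting it never buys a dominant drop
        rel = np.diff(-np.asarray(prof.sse)) / np.asarray(prof.sse)[:-1]
        assert rel.max() < 0.5

    def test_sse_non_increasing_through_true_structure(self):
        X, _ = simulate_tacs(100, noise_sd=0.2, seed=31)
        mat = znormalize(_mat(X))
        prof = elbow_profile(mat, k_max=4, seed=2)
        sse = np.asarray(prof.sse)
        assert np.all(np.diff(sse) <= 1e-6)


class TestAssignment:
    def test_exact_centroid_match(self, labeled_centroids):
        mat = TACMatrix(labeled_centroids.curves[1][None, :],
                        np.zeros((1, 3), int), normalized=True)
        assign = assign_to_centroids(mat, labeled_centroids)
        assert assign.labels[0] == 2
        assert assign.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_tie_goes_to_lowest_label(self):
        c1 = znormalize(_mat([[0, 1, 2, 3.0]])).values[0]
        c3 = c1[::-1].copy()
        c2 = znormalize(_mat([[0, 3, 0, 3.0]])).values[0]
        cs = CentroidSet(np.vstack([c1, c2, c3]),
                         semantic_labels={0: 1, 1: 2, 2: 3})
        # symmetric curve is equidistant from c1 and its mirror c3
        sym = znormalize(_mat([[0, 2, 2, 0.0]]))
        assign = assign_to_centroids(sym, cs)
        d1 = np.linalg.norm(sym.values[0] - c1)
        d3 = np.linalg.norm(sym.values[0] - c3)
        assert d1 == pytest.approx(d3, abs=1e-12)
        assert assign.labels[0] == 1

    def test_length_mismatch_rejected(self, labeled_centroids):
        mat = TACMatrix(np.zeros((1, 7)) + [0, 1, 2, 3, 4, 5, 6.0],
                        np.zeros((1, 3), int))
        with pytest.raises(ValidationError):
            assign_to_centroids(znormalize(mat), labeled_centroids)

    def test_assignment_accuracy_on_phantom_tacs(self, labeled_centroids):
        X, truth = simulate_tacs(100, noise_sd=0.2, seed=77)
        mat = znormalize(_mat(X))
        assign = assign_to_centroids(mat, labeled_centroids)
        assert (assign.labels == truth).mean() >= 0.95


class TestLabelCentroids:
    def test_late_slope_ordering(self, schedule):
        from fetclust.synthetic import make_archetype_curves
        zn = znormalize(_mat(make_archetype_curves(None, schedule)))
        # feed the curves shuffled; labeling must restore canonical order
        cs = label_centroids(CentroidSet(zn.values[[1, 2, 0]]), schedule)
        slopes = cs.metadata["late_slopes_per_hour"]
        assert slopes[0] > 0 > slopes[1] > slopes[2]
        np.testing.assert_allclose(cs.curves[0], zn.values[0], atol=1e-9)
        np.testing.assert_allclose(cs.curves[2], zn.values[2], atol=1e-9)

    def test_k_not_3_rejected(self, schedule):
        with pytest.raises(ValidationError):
            label_centroids(CentroidSet(np.zeros((2, 10))), schedule)

    def test_late_tie_broken_by_early_slope(self, schedule):
        # two curves with *exactly* equal (zero) late slopes but different
        # early rises, plus a clear washout curve
        t = schedule.mid_times
        steep_early = np.where(t < 15, 0.3 * t, 4.5)   # fast rise, flat late
        flat_early = np.where(t < 15, 0.1 * t, 1.5)    # slow rise, flat late
        washout = 3.0 - 0.05 * t
        cs = label_centroids(
            CentroidSet(np.vstack([steep_early, flat_early, washout])),
            schedule)
        # flatter early rise wins label #1, washout gets #3
        np.testing.assert_allclose(cs.curves[0], flat_early, atol=1e-9)
        np.testing.assert_allclose(cs.curves[2], washout, atol=1e-9)

    def test_recovered_labels_match_archetypes(self, labeled_centroids,
                                               schedule):
        from fetclust.synthetic import make_archetype_curves
        truth = znormalize(_mat(make_archetype_curves(None, schedule)))
        assign = assign_to_centroids(truth, labeled_centroids)
        np.testing.assert_array_equal(assign.labels, [1, 2, 3])


def test_proportion_recovery_within_three_points():
    """Mixture weights recovered within +/-3 points at V=2000, noise 0.2."""
    from fetclust.features import centroid_proportions

    X, _ = simulate_tacs(weights=(0.5, 0.3, 0.2), n_total=2000,
                         noise_sd=0.2, seed=3)
    mat = znormalize(_mat(X))
    cs, _, _ = kmeans_dtw(mat, 3, seed=11)
    cs = label_centroids(cs, FrameSchedule.default())
    pct = centroid_proportions(assign_to_centroids(mat, cs))
    for got, want in zip(pct, (50, 30, 20)):
        assert abs(got - want) <= 3.0
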