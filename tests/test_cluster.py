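"""Clustering: PBM selection, fuzzy memberships, density LUT, O-sort."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from measort.core import InputError, TrainingError, UNCLASSIFIED
from measort import cluster as cl


def _blobs(rng, centers, n_per=50, sd=0.1):
    pts = [c + sd * rng.standard_normal((n_per, 3)) for c in
           np.atleast_2d(np.asarray(centers, dtype=float))]
    return np.vstack(pts)


class TestPBM:
    def test_worked_example(self):
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        labels = np.array([0, 0, 1, 1])
        cents = np.array([[0.5], [9.5]])
        # E1 = 18, Ek = 2, Sk = 9 -> ((1/2)(18/2)(9))^2
        assert cl.pbm_index(X, labels, cents) == pytest.approx(1640.25)

    def test_duplication_invariance(self):
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        labels = np.array([0, 0, 1, 1])
        cents = np.array([[0.5], [9.5]])
        a = cl.pbm_index(X, labels, cents)
        b = cl.pbm_index(np.vstack([X, X]), np.tile(labels, 2), cents)
        assert a == pytest.approx(b)

    def test_splitting_a_tight_cluster_lowers_pbm(self):
        """Best K=3 partition of two tight blobs scores below the true
        K=2 partition (brute force over all assignments)."""
        pts = np.array([[0.0], [0.2], [0.4], [9.0], [9.2], [9.4]])

        def score(assign, k):
            labels = np.asarray(assign)
            cents = np.array([pts[labels == i].mean(axis=0)
                              for i in range(k)])
            return cl.pbm_index(pts, labels, cents)

        best2 = score([0, 0, 0, 1, 1, 1], 2)
        best3 = -np.inf
        for assign in itertools.product(range(3), repeat=6):
            if len(set(assign)) == 3:
                best3 = max(best3, score(assign, 3))
        assert best2 > best3

    def test_single_cluster_rejected(self):
        with pytest.raises(InputError):
            cl.pbm_index(np.zeros((4, 1)), np.zeros(4, int),
                         np.zeros((1, 1)))


class TestKMeans:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_cluster_count_and_centers(self, rng, k_true):
        centers = 5.0 * np.eye(3)[:k_true]
        X = _blobs(rng, centers)
        model = cl.kmeans_fit(X, seed=0)
        assert model.k == k_true
        found = sorted(tuple(np.round(c)) for c in model.centroids)
        expect = sorted(tuple(np.round(c)) for c in centers)
        assert found == expect

    def test_deterministic(self, rng):
        X = _blobs(rng, 5.0 * np.eye(3)[:2])
        a = cl.kmeans_fit(X, seed=3)
        b = cl.kmeans_fit(X, seed=3)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_degenerate_data_rejected(self):
        with pytest.raises(TrainingError):
            cl.kmeans_fit(np.ones((20, 3)))

    def test_classify_centroid_and_ties(self):
        model = cl.KMeansModel(centroids=np.array([[0.0, 0, 0],
                                                   [2.0, 0, 0]]), k=2)
        assert cl.kmeans_classify(model, np.array([2.0, 0, 0])) == 1
        assert cl.kmeans_classify(model, np.array([1.0, 0, 0])) == 0  # tie

    def test_never_abstains(self, rng):
        X = _blobs(rng, 5.0 * np.eye(3)[:2])
        model = cl.kmeans_fit(X, seed=0)
        labels = [cl.kmeans_classify(model, x)
                  for x in rng.standard_normal((50, 3)) * 20]
        assert all(l != UNCLASSIFIED for l in labels)


class TestFCM:
    def test_recovers_two_blobs_with_confident_cores(self, rng):
        X = _blobs(rng, [[0, 0, 0], [5, 0, 0]])
        model = cl.fcm_fit(X, m=3.0, seed=0)
        assert model.c == 2
        u = cl.fcm_memberships(model.centers, np.asarray([[0, 0, 0],
                                                          [5, 0, 0]],
                                                         dtype=float), 3.0)
        assert np.all(u.max(axis=0) > 0.9)

    def test_lower_fuzziness_hardens_memberships(self, rng):
        X = _blobs(rng, [[0, 0, 0], [5, 0, 0]])
        probe = X[::7]
        hard = cl.fcm_memberships(cl.fcm_fit(X, m=1.1, seed=0).centers,
                                  probe, 1.1).max(axis=0).mean()
        soft = cl.fcm_memberships(cl.fcm_fit(X, m=3.0, seed=0).centers,
                                  probe, 3.0).max(axis=0).mean()
        assert hard > soft

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 5), st.floats(1.5, 4.0), st.integers(0, 10 ** 6))
    def test_memberships_sum_to_one(self, c, m, seed):
        g = np.random.default_rng(seed)
        centers = g.standard_normal((c, 3))
        X = g.standard_normal((20, 3))
        u = cl.fcm_memberships(centers, X, m)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-9)

    def test_membership_threshold_formula(self):
        for c, expected in ((2, 0.6), (4, 0.35)):
            model = cl.FCMModel(centers=np.zeros((c, 3)), m=3.0, c=c)
            assert model.membership_threshold == pytest.approx(expected)

    def test_defuzzification_abstains_below_threshold(self):
        model = cl.FCMModel(centers=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                            m=3.0, c=2)
        # max membership 0.53 < 0.6 -> unclassified
        assert cl.fcm_classify(model, np.array([0.47, 0, 0])) == UNCLASSIFIED
        # max membership 0.8 >= 0.6 -> assigned
        assert cl.fcm_classify(model, np.array([0.2, 0, 0])) == 0

    def test_center_coincidence_limit(self):
        model = cl.FCMModel(centers=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                            m=3.0, c=2)
        assert cl.fcm_classify(model, np.array([1.0, 0, 0])) == 1

    def test_invalid_fuzziness_rejected(self, rng):
        with pytest.raises(InputError):
            cl.fcm_fit(_blobs(rng, [[0, 0, 0], [5, 0, 0]]), m=1.0)

    def test_agrees_with_kmeans_on_separated_blobs(self, rng):
        """Hard-ish FCM labels match K-means labels on clean blobs."""
        X = _blobs(rng, [[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        km = cl.kmeans_fit(X, seed=0)
        fm = cl.fcm_fit(X, m=1.1, seed=0)
        km_labels = np.array([cl.kmeans_classify(km, x) for x in X])
        u = cl.fcm_memberships(fm.centers, X, fm.m)
        fcm_labels = np.argmax(u, axis=0)
        # compare up to label permutation
        agree = 0
        for perm in itertools.permutations(range(3)):
            mapped = np.array([perm[l] for l in fcm_labels])
            agree = max(agree, float(np.mean(mapped == km_labels)))
        assert agree >= 0.99


class TestDBC:
    def test_two_point_masses_two_clusters(self, rng):
        X = np.vstack([np.zeros((30, 3)), np.full((30, 3), 10.0)])
        X += 0.01 * rng.standard_normal(X.shape)
        model = cl.dbc_train(X, n_levels=16)
        assert model.n_clusters == 2

    def test_single_blob_single_cluster_after_merging(self, rng):
        # sampled densely enough that the cloud's interior is connected
        X = _blobs(rng, [[0, 0, 0]], n_per=1000, sd=1.0)
        model = cl.dbc_train(X, n_levels=16)
        assert model.n_clusters == 1

    def test_resolution_controls_separability(self, rng):
        """Two very close blobs merge at N=16 but split at N=32."""
        X = _blobs(rng, [[0, 0, 0], [1.2, 0, 0]], n_per=400, sd=0.22)
        coarse = cl.dbc_train(X, n_levels=16)
        fine = cl.dbc_train(X, n_levels=32)
        assert fine.n_clusters > coarse.n_clusters or coarse.n_clusters == 1
        assert fine.n_clusters >= 2

    def test_merge_fixpoint_stable(self, rng):
        X = _blobs(rng, [[0, 0, 0]], n_per=300, sd=1.0)
        model = cl.dbc_train(X, n_levels=32)
        again = cl.dbc_merge(model)
        np.testing.assert_array_equal(model.label_lut, again.label_lut)

    def test_classification_is_pure_lookup(self, rng):
        X = _blobs(rng, [[0, 0, 0], [5, 0, 0]])
        model = cl.dbc_train(X, n_levels=16)
        lut_before = model.label_lut.copy()
        f = np.array([0.0, 0.0, 0.0])
        a = cl.dbc_classify(model, f)
        b = cl.dbc_classify(model, f)
        assert a == b
        np.testing.assert_array_equal(model.label_lut, lut_before)

    def test_outside_bounds_unclassified(self, rng):
        X = _blobs(rng, [[0, 0, 0], [5, 0, 0]])
        model = cl.dbc_train(X)
        assert cl.dbc_classify(model, np.array([100.0, 0, 0])) == UNCLASSIFIED

    def test_peak_cell_carries_its_label(self, rng):
        X = _blobs(rng, [[0, 0, 0], [5, 0, 0]])
        model = cl.dbc_train(X, n_levels=16)
        for label, (cell, _) in model.peaks.items():
            assert model.label_lut[cell] == label

    def test_training_points_self_consistent(self, rng):
        """Classification of training points agrees with their basin
        labels (>= 99%)."""
        X = _blobs(rng, [[0, 0, 0], [5, 0, 0]], n_per=200, sd=0.3)
        model = cl.dbc_train(X, n_levels=32)
        agree = 0
        for x in X:
            cell = model.quantize(x)
            assert cell is not None
            agree += cl.dbc_classify(model, x) == model.label_lut[cell]
        assert agree / len(X) >= 0.99
        assert np.mean([cl.dbc_classify(model, x) != UNCLASSIFIED
                        for x in X]) >= 0.95

    def test_degenerate_dimension_rejected(self):
        X = np.zeros((20, 3))
        X[:, 0] = np.arange(20)
        with pytest.raises(TrainingError):
            cl.dbc_train(X)


class TestOSort:
    def _model(self, n=75, sigma2=1.0, c=2.0):
        m = cl.OSortModel(n, correction=c)
        m.sigma2 = sigma2
        return m

    def test_first_spike_founds_cluster(self, rng):
        m = self._model()
        assert m.process(rng.standard_normal(75)) == 0
        assert m.cluster_counts() == {0: 1}

    def test_identical_spike_joins_template(self, rng):
        m = self._model()
        w = 20.0 * rng.standard_normal(75)
        a = m.process(w)
        b = m.process(w.copy())
        assert a == b
        assert m.cluster_counts()[a] == 2

    def test_distant_spike_founds_new_cluster(self, rng):
        m = self._model()
        m.process(np.zeros(75))
        label = m.process(np.full(75, 100.0))
        assert label == 1
        assert len(m.templates) == 2

    def test_drifting_templates_merge(self, rng):
        m = self._model(sigma2=1.0, c=2.0)  # T = 150
        m.process(np.zeros(75))
        w = np.zeros(75)
        w[0] = 10.0  # distance 100 < T: joins and pulls the mean
        lbl = m.process(w)
        assert lbl == 0
        far = np.full(75, 50.0)
        m.process(far)  # separate cluster
        assert len(m.templates) == 2
        # a template drifting towards another within T_S merges
        near_far = far.copy()
        near_far[0] += 5.0
        m.process(near_far)
        assert len(m.templates) == 2  # joined, not new

    def test_threshold_invariant(self, rng):
        m = self._model(sigma2=2.0, c=2.0)
        for _ in range(20):
            m.process(rng.standard_normal(75) * rng.uniform(0, 30))
            assert m.threshold == pytest.approx(2.0 * 75 * 2.0)
        # every processed spike is counted exactly once
        assert sum(m.cluster_counts().values()) == 20

    def test_resolve_labels_follows_merges(self, rng):
        m = self._model()
        raw = [m.process(rng.standard_normal(75) * 30) for _ in range(30)]
        resolved = m.resolve_labels(raw)
        assert set(resolved) <= set(m.templates) | {UNCLASSIFIED}

    def test_variance_tracker_partition_invariant(self, rng):
        x = rng.standard_normal(125000) * 3.0
        a = cl.VarianceTracker(25000.0)
        a.update(x)
        b = cl.VarianceTracker(25000.0)
        for chunk in np.array_split(x, 17):
            b.update(chunk)
        for t in (10, 30000, 99000, 124999):
            assert a.sigma2_at(t) == pytest.approx(b.sigma2_at(t))
        assert a.sigma2_at(124999) == pytest.approx(9.0, rel=0.05)


class TestOSortPrune:
    def test_small_cluster_discarded_boundary_inclusive(self):
        labels = np.array([0] * 4 + [1] * 5 + [2] * 100)
        out = cl.osort_prune(labels, duration_s=60.0)
        assert np.all(out[:4] == UNCLASSIFIED)   # 4 < 5: discarded
        assert np.all(out[4:9] == 1)             # 5 >= 5: kept
        assert np.all(out[9:] == 2)

    def test_threshold_scales_with_duration(self):
        labels = np.array([0] * 7 + [1] * 100)
        out = cl.osort_prune(labels, duration_s=120.0)  # threshold 10
        assert np.all(out[:7] == UNCLASSIFIED)
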