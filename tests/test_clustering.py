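import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from homepatterns.clustering import (
    assign_unseen,
    dunn_index,
    kmeans_fit,
    silhouette_mean,
    som_fit,
)


def brute_force_dunn(X, labels):
    """O(N^2) reference: single-linkage separation over complete diameter."""
    X = np.asarray(X, dtype=float)
    groups = {g: [i for i, l in enumerate(labels) if l == g]
              for g in set(labels)}
    dist = lambda i, j: float(np.linalg.norm(X[i] - X[j]))
    diam = max((max((dist(i, j) for i, j in
                     itertools.combinations(idx, 2)), default=0.0)
                for idx in groups.values()))
    sep = min(dist(i, j)
              for a, b in itertools.combinations(groups, 2)
              for i in groups[a] for j in groups[b])
    return sep / diam


def brute_force_silhouette(X, labels):
    """O(N^2) reference silhouette mean (singletons score 0)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    scores = []
    for i in range(len(X)):
        own = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = min(np.mean([np.linalg.norm(X[i] - X[j])
                         for j in range(len(X)) if labels[j] == g])
                for g in set(labels) if g != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def _blobs(seed=0, n=20, sep=10.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(sep, 1, (n, 3))])
    truth = np.array([0] * n + [1] * n)
    return X, truth


def _same_partition(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return np.array_equal(a, b) or np.array_equal(a, 1 - b)


class TestKMeans:
    def test_k1_centroid_is_the_mean(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        model = kmeans_fit(X, k=1)
        assert np.allclose(model.codebook[0], X.mean(axis=0))

    def test_separated_blobs_recovered(self):
        X, truth = _blobs()
        model = kmeans_fit(X, k=2, seed=0)
        assert _same_partition(model.train_assignments, truth)

    def test_duplicated_rows_same_partition(self):
        X, truth = _blobs()
        doubled = np.vstack([X, X])
        model = kmeans_fit(doubled, k=2, seed=0)
        assert _same_partition(model.train_assignments[:len(X)],
                               model.train_assignments[len(X):])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((1, 2)), k=2)


class TestSOM:
    def test_agrees_with_kmeans_on_blobs(self):
        X, truth = _blobs()
        km = kmeans_fit(X, k=2, seed=0)
        som = som_fit(X, grid=(1, 2), seed=0)
        assert _same_partition(som.train_assignments, km.train_assignments)
        assert _same_partition(som.train_assignments, truth)

    def test_bmu_is_nearest_unit(self):
        X, _ = _blobs(seed=3)
        som = som_fit(X, seed=1)
        d = np.linalg.norm(X[:, None, :] - som.codebook[None, :, :], axis=2)
        assert np.array_equal(som.train_assignments, d.argmin(axis=1))

    def test_fixed_seed_identical_codebook(self):
        X, _ = _blobs(seed=4)
        a = som_fit(X, seed=9)
        b = som_fit(X, seed=9)
        assert np.array_equal(a.codebook, b.codebook)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            som_fit(np.zeros((1, 2)), grid=(1, 2))


class TestAssignment:
    def test_training_rows_keep_their_labels(self):
        X, _ = _blobs(seed=5)
        model = kmeans_fit(X, k=2, seed=0)
        assert np.array_equal(assign_unseen(model, X),
                              model.train_assignments)

    def test_equidistant_point_takes_lower_index(self):
        model = kmeans_fit(np.array([[0.0], [0.0], [2.0], [2.0]]), k=2, seed=0)
        mid = np.array([[model.codebook.mean()]])
        assert assign_unseen(model, mid)[0] == 0

    def test_dimension_mismatch_rejected(self):
        X, _ = _blobs(seed=6)
        model = kmeans_fit(X, k=2, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            assign_unseen(model, X[:, :2])

    def test_fresh_cohort_draw_lands_in_same_clusters(self):
        """Held-out points from the same two blobs join their blob's cluster."""
        X, truth = _blobs(seed=7)
        model = kmeans_fit(X, k=2, seed=0)
        X_new, truth_new = _blobs(seed=8)
        labels_new = assign_unseen(model, X_new)
        # consistent mapping: new points agree with the training partition
        mapping = model.train_assignments[:1][0], model.train_assignments[-1:][0]
        expected = np.where(truth_new == 0, mapping[0], mapping[1])
        assert np.array_equal(labels_new, expected)


class TestValidityIndices:
    def test_dunn_hand_value_on_the_line(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert dunn_index(X, [0, 0, 1, 1]) == pytest.approx(9.0)

    def test_interleaved_clusters_below_one(self):
        X = np.array([[0.0], [1.0], [0.5], [1.5]])
        assert dunn_index(X, [0, 0, 1, 1]) < 1.0

    def test_dunn_scale_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        labels = [0] * 6 + [1] * 6
        assert dunn_index(3.7 * X, labels) == pytest.approx(
            dunn_index(X, labels))

    def test_silhouette_hand_value(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        s0 = (10.5 - 1) / 10.5
        s1 = (9.5 - 1) / 9.5
        assert silhouette_mean(X, [0, 0, 1, 1]) == pytest.approx(
            (s0 + s1) / 2, abs=1e-9)
        assert silhouette_mean(X, [0, 0, 1, 1]) == pytest.approx(0.900, abs=5e-4)

    def test_silhouette_zero_for_identical_mixed_points(self):
        X = np.zeros((6, 2))
        assert silhouette_mean(X, [0, 1, 0, 1, 0, 1]) == 0.0

    def test_silhouette_range(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        labels = rng.integers(0, 3, 15)
        while np.unique(labels).size < 2:
            labels = rng.integers(0, 3, 15)
        assert -1.0 <= silhouette_mean(X, labels) <= 1.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_mean(np.zeros((4, 2)), [0, 0, 0, 0])
        with pytest.raises(ValueError):
            dunn_index(np.zeros((4, 2)), [0, 0, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_both_indices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 25)
        X = rng.normal(size=(n, 3))
        labels = rng.integers(0, 3, n)
        while np.unique(labels).size < 2:
            labels = rng.integers(0, 3, n)
        assert dunn_index(X, labels) == pytest.approx(
            brute_force_dunn(X, labels), abs=1e-10)
        assert silhouette_mean(X, labels) == pytest.approx(
            brute_force_silhouette(X, labels), abs=1e-10)

    def test_silhouette_cross_checked_against_sklearn(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        labels = np.array([0] * 10 + [1] * 10)
        assert silhouette_mean(X, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-10)
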