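"""Weighted k-means: closed forms, exhaustive-partition oracle, reduction to
unweighted k-means, Lloyd monotonicity and the elbow scan contract."""

from itertools import product

import numpy as np
import pytest
from sklearn.cluster import KMeans

from multimorbid.som import train_som
from multimorbid.wkmeans import WeightedKMeans, assign_subjects, elbow_scan, wkmeans


def exhaustive_min_wss(X, w, k):
    """Independent oracle: minimum weighted WSS over every assignment of the
    points to k clusters (feasible only for ~10 points)."""
    X = np.asarray(X, dtype=float)
    best = np.inf
    for assign in product(range(k), repeat=len(X)):
        assign = np.asarray(assign)
        J = 0.0
        for g in range(k):
            mask = assign == g
            wg = w[mask]
            if wg.sum() == 0:
                continue
            c = (wg[:, None] * X[mask]).sum(axis=0) / wg.sum()
            J += float((wg * ((X[mask] - c) ** 2).sum(axis=1)).sum())
        best = min(best, J)
    return best


class TestObjective:
    def test_two_point_closed_form(self):
        # points 0 and 1 with weights 1 and 3: centroid 0.75,
        # J = 1*0.5625 + 3*0.0625 = 0.75
        model = wkmeans(np.array([[0.0], [1.0]]), np.array([1.0, 3.0]), k=1, seed=0)
        assert model.cluster_centers_[0, 0] == pytest.approx(0.75)
        assert model.inertia_ == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_partition_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        X = rng.normal(size=(n, 2))
        w = rng.uniform(0.2, 2.0, size=n)
        model = wkmeans(X, w, k=2, seed=seed, n_restarts=30)
        assert model.inertia_ == pytest.approx(
            exhaustive_min_wss(X, w, 2), rel=1e-9, abs=1e-12
        )

    def test_lloyd_objective_never_increases(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 5))
        w = rng.uniform(0.1, 3.0, size=120)
        model = WeightedKMeans(n_clusters=4, n_restarts=1, random_state=2).fit(
            X, sample_weight=w
        )
        path = np.asarray(model.inertia_path_)
        assert (np.diff(path) <= 1e-9).all()


class TestReductionAndWeights:
    @pytest.mark.parametrize("seed", range(5))
    def test_uniform_weights_reproduce_unweighted_kmeans(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=6.0, size=(3, 4))
        X = np.vstack([rng.normal(loc=c, size=(40, 4)) for c in centers])
        init = X[rng.choice(len(X), size=3, replace=False)]
        ours = WeightedKMeans(n_clusters=3, init=init, random_state=seed).fit(X)
        ref = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300, tol=1e-12).fit(X)
        np.testing.assert_array_equal(ours.labels_, ref.labels_)
        assert ours.inertia_ == pytest.approx(ref.inertia_, rel=1e-9)

    def test_zero_weight_points_assigned_but_inert(self):
        X = np.array([[0.0], [1.0], [100.0]])
        w = np.array([1.0, 1.0, 0.0])
        model = wkmeans(X, w, k=1, seed=0)
        # the far zero-weight point must not move the centroid
        assert model.cluster_centers_[0, 0] == pytest.approx(0.5)
        assert len(model.labels_) == 3
        assert model.inertia_ == pytest.approx(0.5)

    def test_errors(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            wkmeans(X, np.zeros(3), k=1)
        with pytest.raises(ValueError):
            wkmeans(np.arange(6.0).reshape(3, 2), np.array([1.0, 1.0, 0.0]), k=3)


class TestElbow:
    def test_zero_wss_at_k_equal_distinct_points(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5]])
        w = np.ones(4)
        scan = elbow_scan(X, w, 1, 4, seed=0, n_restarts=20)
        assert scan.loc[scan["k"] == 4, "wss"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_wss_non_increasing_in_k(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        w = rng.uniform(0.5, 2.0, size=40)
        scan = elbow_scan(X, w, 1, 8, seed=3, n_restarts=20)
        assert (np.diff(scan["wss"].to_numpy()) <= 1e-9).all()

    def test_planted_codebook_elbows_at_four(self):
        rng = np.random.default_rng(9)
        centers = np.vstack([np.eye(4) * 5, ])
        X = np.vstack([rng.normal(loc=c, scale=0.1, size=(25, 4)) for c in centers])
        w = rng.uniform(0.5, 2.0, size=100)
        scan = elbow_scan(X, w, 1, 8, seed=1, n_restarts=20)
        wss = scan["wss"].to_numpy()
        drops = wss[:-1] - wss[1:]
        # the last big relative drop happens moving to k=4
        assert np.argmax(drops) + 2 <= 4
        assert wss[3] < 0.05 * wss[0]


class TestAssignSubjects:
    def test_subjects_inherit_bmu_cluster_and_partition(self):
        rng = np.random.default_rng(4)
        X = (rng.random((200, 21)) < 0.2).astype(float)
        som = train_som(X, grid_rows=3, grid_cols=3, n_iterations=500, random_state=0)
        sol = wkmeans(som.codebook_, som.activation_counts_.astype(float), k=3, seed=0)
        assignment = assign_subjects(som, sol)
        assert len(assignment) == 200
        np.testing.assert_array_equal(assignment, sol.labels_[som.bmu_index_])
        sizes = np.bincount(assignment, minlength=3)
        assert sizes.sum() == 200

    def test_codebook_mismatch_raises(self):
        rng = np.random.default_rng(5)
        X = (rng.random((50, 21)) < 0.2).astype(float)
        som = train_som(X, grid_rows=2, grid_cols=2, n_iterations=100, random_state=0)
        sol = wkmeans(np.random.default_rng(1).random((9, 21)), np.ones(9), k=2, seed=0)
        with pytest.raises(ValueError):
            assign_subjects(som, sol)
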