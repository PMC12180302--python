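"""Weighted k-means over SOM codebook vectors.

Second stage of the two-level clustering: the codebook vectors are clustered
with k-means in which each node contributes to the objective and to centroid
updates in proportion to its activation frequency (number of subjects whose
BMU it is). Minimizes, locally,

    J = Σ_j w_j · ‖m_j − c_{a(j)}‖²

by Lloyd alternation with weighted-mean centroid updates, initialized by
weighted k-means++ (seeding probability ∝ w_j·D²), best of ``n_restarts``
kept. Zero-weight nodes are excluded from the objective and the updates and
assigned to their nearest centroid afterwards. Subjects inherit the cluster
of their BMU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .som import HexSom


def _weighted_kmeans_pp(X, w, k, rng) -> np.ndarray:
    """k-means++ seeding with selection probability ∝ w · D²."""
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    p = w / w.sum()
    centers[0] = X[rng.choice(n, p=p)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        score = w * d2
        total = score.sum()
        if total <= 0:  # all mass already on chosen points
            centers[i] = X[rng.choice(n, p=p)]
        else:
            centers[i] = X[rng.choice(n, p=score / total)]
        d2 = np.minimum(d2, ((X - centers[i]) ** 2).sum(axis=1))
    return centers


def _lloyd(X, w, k, centers, max_iter, tol=0.0):
    """One weighted Lloyd run; returns (labels, centers, J, J history)."""
    history = []
    labels = None
    for _ in range(max_iter):
        d2 = (
            np.einsum("ij,ij->i", X, X)[:, None]
            - 2.0 * X @ centers.T
            + np.einsum("ij,ij->i", centers, centers)[None, :]
        )
        new_labels = np.argmin(d2, axis=1)
        J = float((w * d2[np.arange(len(X)), new_labels]).sum())
        history.append(J)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for g in range(k):
            mask = labels == g
            wg = w[mask]
            if wg.sum() > 0:
                centers[g] = (wg[:, None] * X[mask]).sum(axis=0) / wg.sum()
            else:
                # re-seed an empty cluster at the worst-fit point
                contrib = w * d2[np.arange(len(X)), labels]
                centers[g] = X[int(np.argmax(contrib))]
    # exact J for the returned state (no cancellation from the expanded form)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    J = float(d2[np.arange(len(X)), labels] @ w)
    return labels, centers, J, history


class WeightedKMeans(BaseEstimator, ClusterMixin):
    """k-means with per-sample weights, weighted k-means++ seeding and
    best-of-restarts selection.

    Parameters
    ----------
    n_clusters : int
    n_restarts : int, default 20
        Independent seedings; the solution with the lowest weighted
        within-cluster sum of squares is kept.
    max_iter : int, default 300
    init : "wkmeans++" or ndarray of shape (n_clusters, n_features)
        An explicit array fixes the initial centroids (restarts collapse
        to a single run).
    random_state : int, default 0

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_features)
    labels_ : ndarray (n_samples,)
    inertia_ : float
        Weighted within-cluster sum of squares of the best run.
    inertia_path_ : list of float
        Objective value per Lloyd iteration of the best run (non-increasing).
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_restarts: int = 20,
        max_iter: int = 300,
        init="wkmeans++",
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None) -> "WeightedKMeans":
        X = check_array(X, dtype=float)
        n = len(X)
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != (n,):
                raise ValueError("sample_weight length must match X")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be at least 1")
        pos = w > 0
        n_pos = int(pos.sum())
        if n_pos == 0:
            raise ValueError("all weights are zero")
        if self.n_clusters > n_pos:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the {n_pos} positive-weight samples"
            )

        Xp, wp = X[pos], w[pos]
        rng = np.random.default_rng(self.random_state)
        explicit_init = not (isinstance(self.init, str) and self.init == "wkmeans++")
        restarts = 1 if explicit_init else self.n_restarts

        best = None
        for _ in range(restarts):
            if explicit_init:
                centers = check_array(np.asarray(self.init, dtype=float)).copy()
                if centers.shape != (self.n_clusters, X.shape[1]):
                    raise ValueError("init array has the wrong shape")
            else:
                centers = _weighted_kmeans_pp(Xp, wp, self.n_clusters, rng)
            labels, centers, J, history = _lloyd(
                Xp, wp, self.n_clusters, centers, self.max_iter
            )
            if best is None or J < best[2]:
                best = (labels, centers, J, history)

        labels_pos, centers, J, history = best
        self.cluster_centers_ = centers
        self.inertia_ = J
        self.inertia_path_ = history
        # zero-weight samples: nearest centroid, no influence on the solution
        labels = np.empty(n, dtype=int)
        labels[pos] = labels_pos
        if (~pos).any():
            d2 = ((X[~pos][:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels[~pos] = np.argmin(d2, axis=1)
        self.labels_ = labels
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def wkmeans(
    codebook, weights, k: int, seed: int = 0, n_restarts: int = 20
) -> WeightedKMeans:
    """Fit weighted k-means on a codebook with node activation weights."""
    return WeightedKMeans(
        n_clusters=k, n_restarts=n_restarts, random_state=seed
    ).fit(np.asarray(codebook, dtype=float), sample_weight=weights)


def elbow_scan(
    codebook, weights, k_min: int = 1, k_max: int = 10, seed: int = 0, n_restarts: int = 20
) -> pd.DataFrame:
    """Weighted WSS per k over [k_min, k_max] under a shared restart policy.

    Returns a DataFrame with columns ``k`` and ``wss`` for elbow inspection.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    # the scan cannot ask for more clusters than active (weight > 0) nodes
    n_pos = int((np.asarray(weights, dtype=float) > 0).sum())
    k_max = min(k_max, n_pos)
    rows = []
    for k in range(k_min, k_max + 1):
        model = wkmeans(codebook, weights, k, seed=seed, n_restarts=n_restarts)
        rows.append({"k": k, "wss": model.inertia_})
    return pd.DataFrame(rows)


def assign_subjects(som: HexSom, solution: WeightedKMeans) -> np.ndarray:
    """Map each subject to the cluster of its BMU node."""
    check_is_fitted(som, "codebook_")
    check_is_fitted(solution, "labels_")
    if len(solution.labels_) != len(som.codebook_):
        raise ValueError("cluster solution was not fitted on this codebook")
    return solution.labels_[som.bmu_index_]
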