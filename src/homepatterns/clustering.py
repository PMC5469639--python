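"""Two-group clustering of participants and cluster validity indices.

K-Means and a small self-organizing map (SOM) partition the participants in
component space; on well-separated data the two methods should agree, which
is itself a robustness check.  The SOM here is deliberately minimal — one
unit per cluster on a 1x2 grid — so its best-matching units play the same
role as K-Means centroids while being trained by competitive learning.

Cluster quality is scored by the Dunn index (minimum single-linkage
between-cluster separation over maximum cluster diameter; higher = compact,
well separated) and the mean silhouette ((b - a)/max(a, b) per point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans


def _as_array(X) -> np.ndarray:
    A = np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValueError("X must be 2-D (rows = participants)")
    return A


@dataclass
class ClusterModel:
    """A fitted 2-group partitioner with a nearest-prototype assignment rule."""

    method: str                 # "KM" or "SOM"
    codebook: np.ndarray        # k x p prototypes (centroids or unit weights)
    train_assignments: np.ndarray

    @property
    def k(self) -> int:
        return self.codebook.shape[0]

    def to_dict(self) -> dict:
        return {"method": self.method, "codebook": self.codebook.tolist(),
                "train_assignments": self.train_assignments.tolist()}


def assign_unseen(model: ClusterModel, X_new) -> np.ndarray:
    """Nearest-prototype (Euclidean) label per row; ties go to the lower index."""
    A = _as_array(X_new)
    if A.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {A.shape[1]} columns,"
            f" codebook has {model.codebook.shape[1]}")
    return np.argmin(cdist(A, model.codebook), axis=1)


def kmeans_fit(X, k: int = 2, restarts: int = 10, seed: int = 0) -> ClusterModel:
    """Lloyd's K-Means, best of ``restarts`` seeded initializations."""
    A = _as_array(X)
    if A.shape[0] < k:
        raise ValueError(f"{A.shape[0]} rows < k = {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                algorithm="lloyd")
    km.fit(A)
    model = ClusterModel("KM", km.cluster_centers_.copy(), km.labels_.copy())
    # enforce the package-wide assignment rule (lowest-index tie-break)
    model.train_assignments = assign_unseen(model, A)
    return model


def som_fit(X, grid: tuple[int, int] = (1, 2), epochs: int = 500,
            lr: tuple[float, float] = (0.5, 0.01),
            radius: tuple[float, float] = (1.0, 0.01),
            seed: int = 0) -> ClusterModel:
    """Online SOM with Gaussian neighbourhood and linear lr/radius decay.

    Units live on a ``grid`` lattice; a row's cluster is its best-matching
    unit.  With the default 1x2 grid the two units act as competitive-
    learning centroids.
    """
    A = _as_array(X)
    rows, cols = grid
    n_units = rows * cols
    if A.shape[0] < n_units:
        raise ValueError(f"{A.shape[0]} rows < {n_units} units")
    rng = np.random.default_rng(seed)
    unit_pos = np.array([(r, c) for r in range(rows) for c in range(cols)],
                        dtype=float)
    grid_d2 = cdist(unit_pos, unit_pos, "sqeuclidean")
    # init: distinct data rows where possible
    init_idx = rng.choice(A.shape[0], size=n_units, replace=A.shape[0] < n_units)
    W = A[init_idx].astype(float).copy()
    lr0, lr1 = lr
    r0, r1 = radius
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        eta = lr0 + frac * (lr1 - lr0)
        sigma = max(r0 + frac * (r1 - r0), 1e-3)
        for i in rng.permutation(A.shape[0]):
            x = A[i]
            bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma ** 2))
            W += eta * h[:, None] * (x - W)
    model = ClusterModel("SOM", W, np.zeros(A.shape[0], dtype=int))
    model.train_assignments = assign_unseen(model, A)
    return model


def _check_labels(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels/rows length mismatch")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 clusters")
    return labels


def dunn_index(X, labels) -> float:
    """Min single-linkage inter-cluster distance over max cluster diameter."""
    A = _as_array(X)
    labels = _check_labels(A, labels)
    D = squareform(pdist(A))
    uniq = np.unique(labels)
    diameters = []
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        diameters.append(D[np.ix_(idx, idx)].max() if idx.size > 1 else 0.0)
    max_diam = max(diameters)
    if max_diam == 0:
        raise ValueError("all clusters are singletons or duplicate points;"
                         " Dunn index undefined")
    seps = []
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            ia = np.flatnonzero(labels == uniq[a])
            ib = np.flatnonzero(labels == uniq[b])
            seps.append(D[np.ix_(ia, ib)].min())
    return float(min(seps) / max_diam)


def silhouette_mean(X, labels) -> float:
    """Mean silhouette (b - a)/max(a, b); singleton clusters score 0."""
    A = _as_array(X)
    labels = _check_labels(A, labels)
    D = squareform(pdist(A))
    n = A.shape[0]
    uniq = np.unique(labels)
    scores = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero(labels == labels[i])
        if own.size == 1:
            continue  # singleton: s = 0
        a = D[i, own[own != i]].mean()
        b = min(D[i, np.flatnonzero(labels == g)].mean()
                for g in uniq if g != labels[i])
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())
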