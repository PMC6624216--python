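"""Clustering backends for anchor cells in feature space (step 4).

Three interchangeable backends behind one contract
``(points, params, seed) -> ClusteringResult``:

* ``kmeans`` — Lloyd iterations with k-means++ seeding, best of
  ``n_restarts`` by within-cluster sum of squares.
* ``kmedoids`` — PAM: medoids are data points; greedy improving swaps on
  the Euclidean distance matrix until no swap lowers the objective.
* ``ap`` — affinity propagation on similarity = negative squared
  Euclidean distance; the cluster count emerges from the preference
  (default: median similarity).

Euclidean geometry on feature rows is the within-space metric
throughout, matching what k-means requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import AffinityPropagation, kmeans_plusplus
from sklearn.exceptions import ConvergenceWarning

from .datamodel import LabelVector, ValidationError

__all__ = ["ClusteringResult", "kmeans", "kmedoids", "affinity_propagation",
           "CLUSTER_BACKENDS", "run_backend"]


@dataclass
class ClusteringResult:
    """Labels plus representative points for one clustering run.

    ``centers`` holds centroids (k-means) or data-point indices
    (k-medoids medoids, AP exemplars). ``converged`` is False only for
    AP runs that hit max_iter without settling.
    """

    labels: LabelVector
    centers: np.ndarray
    backend_tag: str
    seed: int
    objective: float = float("nan")
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return self.labels.n_categories()


def _as_points(features: np.ndarray) -> np.ndarray:
    points = np.asarray(features, dtype=float)
    if points.ndim != 2:
        raise ValidationError("feature rows must form a 2-D matrix")
    if not np.all(np.isfinite(points)):
        raise ValidationError("feature rows must be finite")
    return points


def _wcss(points: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((points - centers[labels]) ** 2).sum())


def kmeans(features: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10,
           tol: float = 1e-6, max_iter: int = 300) -> ClusteringResult:
    """Lloyd's k-means, best of ``n_restarts`` k-means++ starts.

    The within-cluster sum of squares is non-increasing across
    iterations (asserted). A cluster emptied during assignment is
    re-seeded from the point farthest from its current centroid.
    """
    points = _as_points(features)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        restart_seed = int(rng.integers(2**31 - 1))
        centers, _ = kmeans_plusplus(points, n_clusters=k,
                                     random_state=restart_seed)
        prev_obj = np.inf
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            dist2 = cdist(points, centers, metric="sqeuclidean")
            labels = dist2.argmin(axis=1)
            reseeded = False
            for c in range(k):
                if not np.any(labels == c):
                    # re-seed an emptied centroid from the farthest point
                    far = dist2[np.arange(n), labels].argmax()
                    centers[c] = points[far]
                    labels[far] = c
                    reseeded = True
            for c in range(k):
                centers[c] = points[labels == c].mean(axis=0)
            obj = _wcss(points, centers, labels)
            # monotone descent holds for pure Lloyd steps; a re-seed may
            # perturb the objective upward once
            assert reseeded or obj <= prev_obj + 1e-9, \
                "k-means objective increased"
            if prev_obj - obj <= tol:
                prev_obj = obj
                break
            prev_obj = obj
        if best is None or prev_obj < best[0]:
            best = (prev_obj, labels.copy(), centers.copy())
    obj, labels, centers = best
    return ClusteringResult(LabelVector(labels), centers, "kmeans", seed,
                            objective=obj)


def kmedoids(features: np.ndarray, k: int, seed: int = 0,
             max_iter: int = 300) -> ClusteringResult:
    """PAM k-medoids: greedy improving swaps on Euclidean distances.

    Objective = sum of distances from each point to its medoid; the
    returned ``centers`` are medoid indices into the input rows.
    """
    points = _as_points(features)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} must be in [1, {n}]")
    dist = squareform(pdist(points))
    rng = np.random.default_rng(seed)
    # BUILD: greedy — start from the most central point, then add the
    # medoid that most reduces the objective
    medoids = [int(dist.sum(axis=0).argmin())]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[:, None] - dist, 0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    medoids = np.array(sorted(medoids))

    def objective(meds: np.ndarray) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    obj = objective(medoids)
    for _ in range(max_iter):
        improved = False
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        best_swap, best_obj = None, obj
        for mi, m in enumerate(medoids):
            others = np.delete(medoids, mi)
            if others.size:
                base = dist[:, others].min(axis=1)
            else:
                base = np.full(n, np.inf)
            for h in non_medoids:
                cand = float(np.minimum(base, dist[:, h]).sum())
                if cand < best_obj - 1e-12:
                    best_obj, best_swap = cand, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids = medoids.copy()
        medoids[mi] = h
        medoids.sort()
        obj = best_obj
        improved = True
    labels = dist[:, medoids].argmin(axis=1)
    return ClusteringResult(LabelVector(labels), medoids, "kmedoids", seed,
                            objective=obj)


def affinity_propagation(features: np.ndarray, damping: float = 0.9,
                         max_iter: int = 500, convergence_iter: int = 15,
                         preference: float | str = "median",
                         seed: int = 0) -> ClusteringResult:
    """Affinity propagation; the number of clusters emerges from the data.

    Similarity is negative squared Euclidean distance; ``preference``
    defaults to the median similarity. A run that fails to converge
    within ``max_iter`` is returned with ``converged=False`` and a
    warning rather than an exception.
    """
    points = _as_points(features)
    if points.shape[0] < 2:
        raise ValidationError("affinity propagation needs at least 2 points")
    if not 0.5 <= damping < 1.0:
        raise ValidationError(f"damping must be in [0.5, 1), got {damping}")
    pref = None if preference == "median" else float(preference)
    model = AffinityPropagation(damping=damping, max_iter=max_iter,
                                convergence_iter=convergence_iter,
                                preference=pref, affinity="euclidean",
                                random_state=seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(points)
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
    if not converged:
        warnings.warn("affinity propagation did not converge; returning the "
                      "final (non-converged) state", RuntimeWarning,
                      stacklevel=2)
    exemplars = np.asarray(model.cluster_centers_indices_, dtype=int)
    labels = np.asarray(model.labels_, dtype=int)
    if exemplars.size == 0:  # pathological non-convergence: one cluster
        exemplars = np.array([0])
        labels = np.zeros(points.shape[0], dtype=int)
    return ClusteringResult(LabelVector(labels), exemplars, "ap", seed,
                            converged=converged)


CLUSTER_BACKENDS: dict[str, Callable[..., ClusteringResult]] = {
    "kmeans": kmeans,
    "kmedoids": kmedoids,
    "ap": affinity_propagation,
}


def run_backend(backend: str, features: np.ndarray, k: int | None,
                seed: int, **params) -> ClusteringResult:
    """Dispatch to a clustering backend behind the common contract."""
    if backend not in CLUSTER_BACKENDS:
        raise ValidationError(
            f"unknown clustering backend {backend!r}; "
            f"choose from {sorted(CLUSTER_BACKENDS)}"
        )
    if backend == "ap":
        return affinity_propagation(features, seed=seed, **params)
    if k is None:
        raise ValidationError(f"backend {backend!r} requires k")
    return CLUSTER_BACKENDS[backend](features, k, seed=seed, **params)
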