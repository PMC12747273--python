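"""Seeded Lloyd k-means with k-means++ initialisation.

One implementation backs every clustering step in the package (PQ
codebooks, IVF coarse quantisation, mosaic selection, spot clustering) so
they all share the same contract: deterministic under a given Generator,
at most ``max_iter`` Lloyd iterations, and assignment ties broken toward
the lowest centroid id (``argmin`` semantics).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["kmeans", "assign"]


def _kpp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]), dtype=np.float64)
    first = int(rng.integers(n))
    centroids[0] = X[first]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a chosen centroid
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[i] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centroids[i]) ** 2, axis=1))
    return centroids


def assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; ties resolve to the lowest centroid id."""
    return np.argmin(cdist(X, centroids, "sqeuclidean"), axis=1)


def kmeans(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 25,
    n_init: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster ``X`` into ``k`` groups; returns ``(centroids, labels)``.

    ``n_init`` > 1 repeats the whole run from fresh k-means++ seeds and
    keeps the solution with the lowest inertia.  Empty clusters keep
    their previous centroid, so ``k`` centroids are always returned
    (callers that care flag empty clusters themselves).
    """
    X = np.asarray(X, dtype=np.float64)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {X.shape[0]}")
    if n_init > 1:
        best, best_inertia = None, np.inf
        for _ in range(n_init):
            centroids, labels = kmeans(X, k, rng, max_iter=max_iter, n_init=1)
            inertia = float(np.sum((X - centroids[labels]) ** 2))
            if inertia < best_inertia:
                best, best_inertia = (centroids, labels), inertia
        return best
    centroids = _kpp_init(X, k, rng)
    labels = assign(X, centroids)
    for _ in range(max_iter):
        new = centroids.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members):
                new[j] = members.mean(axis=0)
        new_labels = assign(X, new)
        converged = np.array_equal(new_labels, labels) and np.allclose(new, centroids)
        centroids, labels = new, new_labels
        if converged:
            break
    return centroids, labels
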