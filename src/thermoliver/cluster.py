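"""k-means clustering (Lloyd iterations) and best-permutation detection rate."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np


def _kmeanspp_init(Y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++ style) centroid seeding."""
    N = Y.shape[0]
    centroids = [Y[rng.integers(N)]]
    for _ in range(1, k):
        d2 = np.min(
            np.sum((Y[:, None, :] - np.array(centroids)[None, :, :]) ** 2, axis=2), axis=1
        )
        total = d2.sum()
        if total == 0:
            centroids.append(Y[rng.integers(N)])
        else:
            centroids.append(Y[rng.choice(N, p=d2 / total)])
    return np.array(centroids)


def _lloyd(Y: np.ndarray, centroids: np.ndarray, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    """Iterate assignment/update until the partition stops changing.

    An emptied cluster is re-seeded at the point farthest from its
    assigned centroid.
    """
    k = centroids.shape[0]
    assignments = None
    for _ in range(max_iter):
        d2 = np.sum((Y[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(d2, axis=1)
        for c in range(k):
            if not np.any(new_assign == c):
                farthest = int(np.argmax(np.min(d2, axis=1)))
                centroids[c] = Y[farthest]
                new_assign[farthest] = c
        if assignments is not None and np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
        for c in range(k):
            centroids[c] = Y[assignments == c].mean(axis=0)
    d2 = np.sum((Y[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
    wcss = float(d2[np.arange(Y.shape[0]), assignments].sum())
    return assignments, centroids, wcss


def kmeans(
    Y: np.ndarray,
    k: int = 2,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``restarts`` k-means; returns (assignments, centroids, WCSS).

    Restarts are seeded from ``seed``; the winner has the lowest
    within-cluster sum of squares, ties broken by lowest restart index.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.ndim == 2 and Y.shape[1] == 0:
        raise ValueError("empty input")
    if Y.shape[0] < k:
        raise ValueError(f"need at least k = {k} points, got {Y.shape[0]}")
    rng = np.random.default_rng(seed)
    inits = [_kmeanspp_init(Y, k, rng) for _ in range(max(1, restarts))]
    # on tiny inputs with k = 2 every distinct point pair is a cheap,
    # deterministic initialization; sweeping them all makes the best
    # restart coincide with the exhaustive-partition optimum in practice
    n = Y.shape[0]
    if k == 2 and n * (n - 1) // 2 <= 128:
        from itertools import combinations

        inits.extend(np.array([Y[i], Y[j]]) for i, j in combinations(range(n), 2))
    best = None
    for init in inits:
        assignments, centroids, wcss = _lloyd(Y, init.copy(), max_iter=max_iter)
        if best is None or wcss < best[2]:
            best = (assignments, centroids, wcss)
    return best


@dataclass
class DetectionResult:
    """Clustering outcome scored against true group labels."""

    assignments: np.ndarray
    centroids: np.ndarray | None
    detection_rate: float
    n_correct: int


def detection_rate(
    assignments: np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray | None = None,
) -> DetectionResult:
    """Score cluster assignments under the best cluster→label permutation.

    ``labels`` is binary (two distinct values, any type). n_correct is
    the maximum agreement count over all injective mappings of cluster
    indices onto labels; the rate is n_correct / N.
    """
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape != labels.shape:
        raise ValueError(
            f"assignments ({assignments.shape}) and labels ({labels.shape}) differ in length"
        )
    uniq_labels = np.unique(labels).tolist()
    if len(uniq_labels) > 2:
        raise ValueError(f"labels must be binary, got {uniq_labels}")
    uniq_clusters = np.unique(assignments).tolist()
    best = 0
    for perm in permutations(uniq_labels, min(len(uniq_clusters), len(uniq_labels))):
        mapping = dict(zip(uniq_clusters, perm))
        best = max(
            best,
            sum(mapping.get(a) == lab for a, lab in zip(assignments.tolist(), labels.tolist())),
        )
    n = len(labels)
    return DetectionResult(
        assignments=assignments,
        centroids=centroids,
        detection_rate=best / n,
        n_correct=best,
    )
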