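"""Lloyd-style K-means with the SSE objective shared by the swarm optimizer.

The engine is written in plain numpy on purpose: the same
:func:`sse_objective` is the fitness function the particle swarm minimizes,
and the swarm's best centroid set is handed back here for a final
refinement, so both engines must agree exactly on the objective,
assignment rule and tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CentroidSet:
    """k centroids of dimension dim, stored as a (k, dim) array."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if not np.all(np.isfinite(centers)):
            raise ValueError("centroids must be finite")
        object.__setattr__(self, "centers", centers)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    @classmethod
    def from_flat(cls, flat: np.ndarray, k: int) -> "CentroidSet":
        """Decode a flattened particle position of length k*dim."""
        flat = np.asarray(flat, dtype=float)
        return cls(flat.reshape(k, -1))

    def to_flat(self) -> np.ndarray:
        return self.centers.ravel().copy()


@dataclass
class Partition:
    """Result of a clustering run: assignment, centroids and the SSE."""

    assignment: np.ndarray
    centroids: CentroidSet
    sse: float
    n_iter: int = 0
    sse_history: tuple = ()

    @property
    def k(self) -> int:
        return self.centroids.k


def _check_dims(points: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if points.shape[1] != centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: points have dim {points.shape[1]}, "
            f"centroids dim {centers.shape[1]}"
        )
    return points, centers


def _sq_dists(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances
    diff = points[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def assign_to_nearest(points: np.ndarray, centroids: CentroidSet | np.ndarray) -> np.ndarray:
    """Index of the nearest centroid per point; ties go to the lowest index."""
    centers = centroids.centers if isinstance(centroids, CentroidSet) else centroids
    points, centers = _check_dims(points, centers)
    return np.argmin(_sq_dists(points, centers), axis=1)


def sse_objective(points: np.ndarray, centroids: CentroidSet | np.ndarray) -> float:
    """Sum over points of the squared Euclidean distance to the nearest centroid."""
    centers = centroids.centers if isinstance(centroids, CentroidSet) else centroids
    points, centers = _check_dims(points, centers)
    return float(np.min(_sq_dists(points, centers), axis=1).sum())


def kmeans(
    points: np.ndarray,
    k: int,
    init: CentroidSet | np.ndarray | None = None,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Partition:
    """Cluster points into k groups by alternating assignment and update.

    Parameters
    ----------
    points : (n, dim) array
    k : number of clusters; must not exceed the number of distinct points.
    init : explicit initial centroids; if omitted, k distinct data points
        are chosen uniformly at random under ``seed``.
    max_iter : iteration cap.
    tol : relative SSE improvement below which iteration stops.

    The SSE is non-increasing across iterations. A cluster left empty by an
    assignment step is repaired by re-seeding its centroid at the point
    currently farthest from its own centroid.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    distinct = np.unique(points, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(f"k={k} exceeds the {distinct.shape[0]} distinct points")
    if k < 1:
        raise ValueError("k must be >= 1")

    if init is None:
        rng = np.random.default_rng(seed)
        centers = distinct[rng.choice(distinct.shape[0], size=k, replace=False)].copy()
    else:
        centers = (init.centers if isinstance(init, CentroidSet) else np.atleast_2d(np.asarray(init, dtype=float))).copy()
        _check_dims(points, centers)
        if centers.shape[0] != k:
            raise ValueError(f"init has {centers.shape[0]} centroids, expected {k}")

    assignment = assign_to_nearest(points, centers)
    history: list[float] = []
    prev_sse = np.inf
    for it in range(1, max_iter + 1):
        # update step: each centroid moves to its cluster mean
        for j in range(k):
            mask = assignment == j
            if mask.any():
                centers[j] = points[mask].mean(axis=0)
            else:
                # empty-cluster repair: grab the globally worst-fit point
                d = np.min(_sq_dists(points, centers), axis=1)
                centers[j] = points[np.argmax(d)]
        new_assignment = assign_to_nearest(points, centers)
        sse = sse_objective(points, centers)
        history.append(sse)
        unchanged = np.array_equal(new_assignment, assignment)
        assignment = new_assignment
        if unchanged:
            break
        if np.isfinite(prev_sse) and prev_sse > 0 and (prev_sse - sse) / prev_sse < tol:
            break
        prev_sse = sse

    final_sse = sse_objective(points, centers)
    return Partition(
        assignment=assignment,
        centroids=CentroidSet(centers),
        sse=final_sse,
        n_iter=len(history),
        sse_history=tuple(history),
    )


def standardize(points: np.ndarray) -> np.ndarray:
    """Column-wise z-scores; constant columns map to zero.

    Clustering operates on standardized physical features by default:
    height in meters spans ~0.4 units while weight in kilograms spans ~50,
    so raw Euclidean distances would ignore height entirely.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    mu = points.mean(axis=0)
    sd = points.std(axis=0)
    sd[sd == 0] = 1.0
    return (points - mu) / sd
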