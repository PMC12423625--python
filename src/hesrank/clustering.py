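"""Ordered performance tiers via K-means on composite scores.

Countries are partitioned into K tiers (default K=5) by K-means on their
one-dimensional composite scores.  In 1-D the sum-of-squared-deviations
optimum is a contiguous partition of the sorted values, so the default
solver finds it exactly by dynamic programming over segment boundaries —
no initialisation, no seed sensitivity.  A Lloyd/k-means++ solver is kept
alongside for parity-checking against conventional K-means tooling.

Tiers are ordered by descending centroid: level 1 ("High") holds the
best performers down to level K ("Dangerous").  Partitions are validated
with the mean silhouette coefficient s(i) = (b - a) / max(a, b).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "DEFAULT_LEVEL_NAMES",
    "TierAssignment",
    "kmeans_1d_optimal",
    "kmeans_lloyd",
    "assign_levels",
    "silhouette_mean",
    "attach_silhouette",
]

DEFAULT_LEVEL_NAMES = ("High", "Safe", "Intermediate", "Warning", "Dangerous")

#: accepted synonyms when naming levels from user input
LEVEL_NAME_ALIASES = {"Alert": "Warning", "Moderate": "Intermediate"}


@dataclass(frozen=True)
class TierAssignment:
    """A K-cluster partition of 1-D scores with ordered levels.

    ``labels[i]`` is the cluster index of ``values[i]``;
    ``level_by_cluster`` maps each cluster index to its level (1 = highest
    centroid).  ``inertia`` is the within-cluster sum of squares.
    """

    values: np.ndarray
    labels: np.ndarray
    centroids: np.ndarray
    K: int
    countries: tuple[str, ...] | None = None
    level_by_cluster: tuple[int, ...] | None = None
    level_names: tuple[str, ...] | None = None
    silhouette_mean: float | None = None
    per_point_silhouette: np.ndarray | None = None
    seed: int | None = None

    @property
    def inertia(self) -> float:
        return float(((self.values - self.centroids[self.labels]) ** 2).sum())

    @property
    def levels(self) -> np.ndarray:
        """Level number (1..K) per point; requires :func:`assign_levels`."""
        if self.level_by_cluster is None:
            raise ValueError("levels not assigned yet; call assign_levels()")
        mapping = np.asarray(self.level_by_cluster)
        return mapping[self.labels]

    def members(self, level: int) -> list[str]:
        """Country names in a given level, in input order."""
        if self.countries is None:
            raise ValueError("no country names attached to this assignment")
        mask = self.levels == level
        return [c for c, keep in zip(self.countries, mask) if keep]

    def level_name(self, level: int) -> str:
        if self.level_names is None:
            raise ValueError("levels not assigned yet; call assign_levels()")
        return self.level_names[level - 1]


def _validate_inputs(values: np.ndarray, K: int) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    distinct = np.unique(values).size
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > distinct:
        raise ValueError(
            f"K={K} exceeds the number of distinct values ({distinct})"
        )
    return values


def kmeans_1d_optimal(
    values: Sequence[float] | np.ndarray,
    K: int = 5,
    countries: Sequence[str] | None = None,
) -> TierAssignment:
    """Globally optimal 1-D K-means by dynamic programming.

    Minimises the within-cluster sum of squares over all partitions; the
    optimum is contiguous in sorted order, so a DP over segment
    boundaries with prefix-sum segment costs finds it exactly in
    O(K m^2).  Deterministic: no initialisation or seed.
    """
    values = _validate_inputs(np.asarray(values), K)
    m = values.size
    order = np.argsort(values, kind="stable")
    x = values[order]

    # segment cost: sum of squared deviations of x[i..j] about its mean
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:  # inclusive endpoints
        s = pref[j + 1] - pref[i]
        s2 = pref2[j + 1] - pref2[i]
        n = j - i + 1
        return s2 - s * s / n

    INF = float("inf")
    cost = np.full((K + 1, m + 1), INF)
    split = np.zeros((K + 1, m + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, m + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + seg_cost(i, j - 1)
                if c < best:
                    best, arg = c, i
            cost[k, j] = best
            split[k, j] = arg

    # walk back the segment boundaries
    bounds = [m]
    j = m
    for k in range(K, 0, -1):
        j = split[k, j]
        bounds.append(j)
    bounds.reverse()

    sorted_labels = np.empty(m, dtype=int)
    centroids = np.empty(K)
    for k in range(K):
        lo, hi = bounds[k], bounds[k + 1]
        sorted_labels[lo:hi] = k
        centroids[k] = x[lo:hi].mean()
    labels = np.empty(m, dtype=int)
    labels[order] = sorted_labels
    return TierAssignment(
        values=values,
        labels=labels,
        centroids=centroids,
        K=K,
        countries=tuple(countries) if countries is not None else None,
    )


def kmeans_lloyd(
    values: Sequence[float] | np.ndarray,
    K: int = 5,
    seed: int = 42,
    restarts: int = 100,
    countries: Sequence[str] | None = None,
) -> TierAssignment:
    """Lloyd's algorithm with k-means++ initialisation, best of ``restarts``.

    Provided for parity-checking the exact DP solver against conventional
    K-means; deterministic under a fixed seed.
    """
    values = _validate_inputs(np.asarray(values), K)
    km = KMeans(n_clusters=K, init="k-means++", n_init=restarts,
                random_state=seed).fit(values.reshape(-1, 1))
    return TierAssignment(
        values=values,
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_.ravel(),
        K=K,
        countries=tuple(countries) if countries is not None else None,
        seed=seed,
    )


def assign_levels(
    assignment: TierAssignment,
    names: Sequence[str] | None = None,
) -> TierAssignment:
    """Order clusters into levels 1..K by strictly descending centroid.

    The cluster with the largest centroid becomes level 1 and takes the
    first name.  ``names`` defaults to High / Safe / Intermediate /
    Warning / Dangerous for K=5 and to "Level i" otherwise; "Alert" and
    "Moderate" are accepted aliases for Warning and Intermediate.
    """
    K = assignment.K
    if names is None:
        names = DEFAULT_LEVEL_NAMES if K == 5 else tuple(
            f"Level {i + 1}" for i in range(K)
        )
    names = tuple(LEVEL_NAME_ALIASES.get(n, n) for n in names)
    if len(names) != K:
        raise ValueError(f"need {K} level names, got {len(names)}")
    order = np.argsort(-assignment.centroids, kind="stable")
    level_by_cluster = np.empty(K, dtype=int)
    for level, cluster in enumerate(order, start=1):
        level_by_cluster[cluster] = level
    return replace(
        assignment,
        level_by_cluster=tuple(int(v) for v in level_by_cluster),
        level_names=tuple(names),
    )


def silhouette_mean(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean and per-point silhouette of a 1-D partition.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean
    within-cluster distance (self excluded), b(i) the smallest mean
    distance to another cluster; Euclidean distance on the score line.
    Points in singleton clusters get s(i) = 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    dist = np.abs(values[:, None] - values[None, :])
    s = np.zeros(values.size)
    sizes = {c: int((labels == c).sum()) for c in clusters}
    for i in range(values.size):
        own = labels[i]
        if sizes[own] == 1:
            continue
        mask_own = labels == own
        a = dist[i, mask_own].sum() / (sizes[own] - 1)
        b = min(
            dist[i, labels == other].mean()
            for other in clusters
            if other != own
        )
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return float(s.mean()), s


def attach_silhouette(assignment: TierAssignment) -> TierAssignment:
    """Return a copy with silhouette statistics filled in."""
    mean, per_point = silhouette_mean(assignment.values, assignment.labels)
    return replace(assignment, silhouette_mean=mean, per_point_silhouette=per_point)
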