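"""Partitioning Around Medoids (PAM) on a precomputed dissimilarity matrix.

Classical deterministic k-medoids: a greedy BUILD phase seeds the medoids
(first the point minimizing total distance to all others, then repeatedly the
point whose addition most reduces total cost), and a SWAP phase repeatedly
applies the single best (medoid, non-medoid) exchange as long as it strictly
reduces the total cost. No random restarts — the result is a pure function of
the distance matrix, so a clustering is reproducible without seeds.

Cluster-number selection maximizes the Average Silhouette Width (ASW): for
each point, s(i) = (b(i) - a(i)) / max(a(i), b(i)) where a(i) is the mean
distance to the point's own cluster (excluding itself) and b(i) the smallest
mean distance to any other cluster; ASW is the mean of s(i). ASW near 1
indicates tight, well-separated clusters; near 0, overlapping structure.
Singleton clusters get s(i) = 0 by convention.

The SWAP deltas for all (medoid, candidate) pairs are evaluated in O(n^2)
per iteration using the nearest/second-nearest medoid decomposition, which
keeps full k-range searches on panels of a few thousand sequences cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dissimilarity import DissimilarityMatrix


@dataclass
class ClusterSolution:
    """One PAM solution: medoids, assignments, cost, and silhouette quality.

    ``labels[i]`` is the index into ``medoid_indices`` of subject i's medoid;
    every subject is assigned to its nearest medoid (ties to the lowest
    medoid index) and each medoid to itself, so
    ``total_cost = sum_i d(i, medoid(i))``.
    """

    k: int
    medoid_indices: np.ndarray
    labels: np.ndarray
    total_cost: float
    asw: float | None = None
    ids: list[str] = field(default_factory=list)

    @property
    def medoid_ids(self) -> list[str]:
        return [self.ids[m] for m in self.medoid_indices] if self.ids else []

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment; ties to the lowest medoid index (argmin)."""
    dm = d[:, medoids]
    labels = np.argmin(dm, axis=1)
    cost = float(dm[np.arange(d.shape[0]), labels].sum())
    return labels, cost


def _build(d: np.ndarray, k: int) -> np.ndarray:
    """Greedy seeding: first medoid minimizes total distance, then max cost drop."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    dnear = d[:, medoids[0]].copy()
    for _ in range(1, k):
        # gain[j] = total cost reduction from adding candidate j
        gain = np.maximum(dnear[:, None] - d, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        j = int(np.argmax(gain))
        medoids.append(j)
        dnear = np.minimum(dnear, d[:, j])
    return np.array(sorted(medoids), dtype=np.int64)


def _swap_deltas(d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Cost change of every (medoid slot, candidate point) exchange.

    Decomposition over each point i with nearest-medoid distance dn_i and
    second-nearest ds_i: replacing a medoid m by candidate h changes i's
    contribution by min(d(i,h), dn_i) - dn_i when m is not i's medoid, and by
    min(d(i,h), ds_i) - dn_i when it is. Returns a (k, n) array; columns of
    current medoids are +inf (not exchangeable with themselves).
    """
    n = d.shape[0]
    k = len(medoids)
    dm = d[:, medoids]
    order = np.argsort(dm, kind="stable", axis=1)
    nearest = order[:, 0]
    dnear = dm[np.arange(n), nearest]
    dsecond = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)

    # shared term: applies to every removed medoid that is not i's own
    shared = np.minimum(d - dnear[:, None], 0.0)  # (i, h)
    base = shared.sum(axis=0)  # (h,)
    # correction when the removed medoid *is* i's own
    own = np.minimum(d, dsecond[:, None]) - dnear[:, None] - shared  # (i, h)

    deltas = np.empty((k, n))
    for slot in range(k):
        mask = nearest == slot
        deltas[slot] = base + own[mask].sum(axis=0)
    deltas[:, medoids] = np.inf
    return deltas


def pam(D: DissimilarityMatrix, k: int, max_swaps: int = 1000) -> ClusterSolution:
    """Run BUILD + SWAP k-medoids; deterministic for a fixed input.

    Equal-gain swaps are not taken (strict improvement only), so the total
    cost strictly decreases at every swap and the algorithm terminates.
    """
    d = D.values
    n = D.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")

    medoids = _build(d, k)
    labels, cost = _assign(d, medoids)

    for _ in range(max_swaps):
        if k == n:
            break
        deltas = _swap_deltas(d, medoids)
        slot, h = np.unravel_index(np.argmin(deltas), deltas.shape)
        if deltas[slot, h] >= -1e-12:  # no strictly improving swap left
            break
        medoids = medoids.copy()
        medoids[slot] = h
        medoids.sort()
        labels, cost = _assign(d, medoids)

    sol = ClusterSolution(
        k=k,
        medoid_indices=medoids,
        labels=labels,
        total_cost=cost,
        ids=list(D.ids),
    )
    if 2 <= k:
        sol.asw = asw(D, labels)
    return sol


def silhouette(D: DissimilarityMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette widths s(i); singleton clusters get s(i) = 0."""
    labels = np.asarray(labels)
    d = D.values
    n = d.shape[0]
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} != ({n},)")
    uniq, inv = np.unique(labels, return_inverse=True)
    kk = len(uniq)
    if kk < 2:
        raise ValueError("silhouette requires at least 2 clusters")

    # mean distance from each point to each cluster
    member = np.zeros((n, kk))
    member[np.arange(n), inv] = 1.0
    sizes = member.sum(axis=0)
    sums = d @ member  # (n, kk) sum of distances to each cluster

    own_size = sizes[inv]
    a = np.where(own_size > 1, sums[np.arange(n), inv] / np.maximum(own_size - 1, 1), 0.0)
    mean_other = sums / sizes[None, :]
    mean_other[np.arange(n), inv] = np.inf
    b = mean_other.min(axis=1)

    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s[own_size == 1] = 0.0
    return s


def asw(D: DissimilarityMatrix, labels: np.ndarray) -> float:
    """Average Silhouette Width — mean of s(i), bounded in [-1, 1]."""
    return float(silhouette(D, labels).mean())


def select_k(
    D: DissimilarityMatrix,
    k_min: int = 2,
    k_max: int = 10,
    max_swaps: int = 1000,
) -> tuple[ClusterSolution, dict[int, float]]:
    """Run PAM over a k range and keep the solution with the highest ASW.

    Returns the best solution plus the full k -> ASW profile. Ties go to the
    smaller k (the more parsimonious typology).
    """
    if k_min > k_max:
        raise ValueError(f"empty k range [{k_min}, {k_max}]")
    if k_max > D.n:
        raise ValueError(f"k_max={k_max} exceeds number of sequences {D.n}")
    if k_min < 2:
        raise ValueError("k_min must be >= 2 (ASW is undefined for one cluster)")

    profile: dict[int, float] = {}
    best: ClusterSolution | None = None
    for k in range(k_min, k_max + 1):
        sol = pam(D, k, max_swaps=max_swaps)
        profile[k] = sol.asw  # type: ignore[assignment]
        if best is None or sol.asw > best.asw + 1e-12:  # strict: ties keep smaller k
            best = sol
    assert best is not None
    return best, profile
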