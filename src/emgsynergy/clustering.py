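"""Clustering the population of spatial synergies and choosing its order.

All extracted synergy vectors (unit-norm, one per module) are pooled into a
single population and clustered with k-means (Lloyd's algorithm, Euclidean
distance, many random restarts) at every order k from 1 to k_max. The
quality index is the Mean Euclidean Distance (MED) of the population from
its assigned centroids; the Normalized Euclidean Distance NED(k) =
MED(k)/MED(1) rescales it so that approximating the whole population by its
mean (k = 1) is the maximum error, 1. The number of mean spatial synergies
is the smallest k with NED below a tolerance (5 % by default): the most
parsimonious description within the accepted reconstruction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import SynergySet

_MAX_LLOYD_ITER = 300


@dataclass
class SynergyPopulation:
    """The pooled population of extracted spatial synergies.

    ``vectors`` is (M, channels), one unit-norm row per module;
    ``provenance`` records (subject_id, grasp_id, synergy_index) per row so
    temporal components can be traced back after clustering.
    """

    vectors: np.ndarray
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.provenance and len(self.provenance) != self.vectors.shape[0]:
            raise ValueError("provenance length must match vector count")

    @property
    def size(self) -> int:
        return self.vectors.shape[0]


@dataclass
class ClusterSolution:
    """Best-of-restarts k-means solution at one clustering order."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    med: float
    ned: float = np.nan
    ned_slope: float = np.nan
    seed: int = 0


def build_population(synergy_sets: list[SynergySet]) -> SynergyPopulation:
    """Pool the spatial synergies of all sets into one population."""
    rows = []
    prov = []
    for ss in synergy_sets:
        for j in range(ss.N):
            rows.append(ss.W[:, j])
            prov.append((ss.subject_id, ss.grasp_id, j))
    if not rows:
        raise ValueError("no synergies to pool")
    return SynergyPopulation(vectors=np.asarray(rows), provenance=prov)


def med(
    pop: SynergyPopulation | np.ndarray,
    centroids: np.ndarray,
    assignments: np.ndarray,
) -> float:
    """Mean Euclidean distance of every point to its assigned centroid."""
    X = pop.vectors if isinstance(pop, SynergyPopulation) else np.asarray(pop)
    centroids = np.asarray(centroids)
    assignments = np.asarray(assignments, dtype=int)
    if X.shape[0] != assignments.shape[0]:
        raise ValueError("one assignment per population row required")
    if X.shape[1] != centroids.shape[1]:
        raise ValueError("centroid and population dimensions differ")
    d = np.linalg.norm(X - centroids[assignments], axis=1)
    return float(d.mean())


def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # ties broken toward the lowest centroid index (argmin convention)
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _kmeanspp_init(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ D² seeding: spread the initial centroids over the data."""
    M = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(M)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centroids[j:] = X[rng.choice(M, size=k - j, replace=False)]
            break
        centroids[j] = X[rng.choice(M, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    centroids = _kmeanspp_init(X, k, rng)
    assignments = _assign(X, centroids)
    for _ in range(_MAX_LLOYD_ITER):
        for j in range(k):
            members = assignments == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                # repair: reseed the empty cluster with the point farthest
                # from its current centroid
                dist = np.linalg.norm(X - centroids[assignments], axis=1)
                far = int(dist.argmax())
                centroids[j] = X[far]
                assignments[far] = j
        new = _assign(X, centroids)
        if np.array_equal(new, assignments):
            break
        assignments = new
    # final means, so centroids are exact member averages
    for j in range(k):
        members = assignments == j
        if members.any():
            centroids[j] = X[members].mean(axis=0)
    return centroids, assignments


def kmeans_cluster(
    pop: SynergyPopulation,
    k: int,
    n_repeats: int = 200,
    seed: int = 0,
) -> ClusterSolution:
    """Best of ``n_repeats`` k-means++-seeded Lloyd restarts, by lowest MED.

    Restart seeds are derived from (seed, k, repeat index) so any single
    restart can be reproduced in isolation. Every cluster is guaranteed
    nonempty via farthest-point reseeding.
    """
    X = pop.vectors
    if not 1 <= k <= pop.size:
        raise ValueError(f"k={k} out of range 1..{pop.size}")
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, k, rep)))
        centroids, assignments = _lloyd(X, k, rng)
        m = med(pop, centroids, assignments)
        if best is None or m < best[0]:
            best = (m, centroids, assignments)
    m, centroids, assignments = best
    return ClusterSolution(
        k=k, centroids=centroids, assignments=assignments, med=m, seed=seed
    )


@dataclass
class NEDCurve:
    """MED/NED/NED′ across clustering orders, with the per-order solutions."""

    table: pd.DataFrame
    solutions: dict[int, ClusterSolution]


def ned_curve(
    pop: SynergyPopulation,
    k_max: int = 50,
    n_repeats: int = 200,
    seed: int = 0,
) -> NEDCurve:
    """Cluster at k = 1..k_max and tabulate (k, MED, NED, NED′).

    NED(k) = MED(k)/MED(1), so NED(1) = 1 exactly; NED′ is the backward
    difference NED(k) − NED(k−1) on the integer k axis (NaN at k = 1).
    """
    if k_max > pop.size:
        raise ValueError(f"k_max={k_max} exceeds population size {pop.size}")
    solutions: dict[int, ClusterSolution] = {}
    meds = np.empty(k_max)
    for k in range(1, k_max + 1):
        sol = kmeans_cluster(pop, k, n_repeats=n_repeats, seed=seed)
        solutions[k] = sol
        meds[k - 1] = sol.med
    if meds[0] == 0.0:
        raise ValueError(
            "MED(1) = 0: all synergy vectors are identical, clustering is "
            "meaningless for this population"
        )
    ned = meds / meds[0]
    slope = np.concatenate(([np.nan], np.diff(ned)))
    for k in range(1, k_max + 1):
        solutions[k].ned = float(ned[k - 1])
        solutions[k].ned_slope = float(slope[k - 1])
    table = pd.DataFrame(
        {"k": np.arange(1, k_max + 1), "MED": meds, "NED": ned, "NED_slope": slope}
    )
    return NEDCurve(table=table, solutions=solutions)


def select_cluster_order(
    curve: NEDCurve | pd.DataFrame, threshold: float = 0.05
) -> int:
    """Smallest k with NED strictly below the threshold.

    Falls back to the largest tested k with a warning when the threshold is
    never reached.
    """
    table = curve.table if isinstance(curve, NEDCurve) else curve
    if len(table) == 0:
        raise ValueError("empty NED curve")
    below = table.loc[table["NED"] < threshold, "k"]
    if len(below):
        return int(below.iloc[0])
    k_max = int(table["k"].max())
    warnings.warn(
        f"NED never fell below {threshold}; returning k_max={k_max}",
        stacklevel=2,
    )
    return k_max
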