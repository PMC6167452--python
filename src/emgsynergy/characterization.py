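"""Spatial and temporal characterization of the clustered synergies.

Once the population of spatial synergies has been reduced to k mean
spatial synergies (centroids), three views summarize the solution: the
pairwise dot products of the unit-normalized centroid directions (how much
muscle weighting the mean modules share); each centroid's mean temporal
component, the pointwise average of the activation curves of all member
synergies (when in the grasp phase the module is recruited); and the
Pearson correlation matrix of those mean temporal components. A separate
per-grasp view matches each subject's synergies to a reference subject's
by temporal-component correlation and averages the matched modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .clustering import ClusterSolution, SynergyPopulation
from .extraction import SynergySet


@dataclass
class CentroidProfile:
    """One mean spatial synergy with its population share and activation."""

    centroid: np.ndarray
    share: float  # percent of the population assigned to this centroid
    mean_temporal: np.ndarray
    member_temporals: list[np.ndarray] = field(default_factory=list)


def centroid_dot_matrix(centroids: np.ndarray) -> np.ndarray:
    """Pairwise dot products of unit-normalized centroid directions.

    Centroids are means of unit vectors and hence slightly shorter than
    unit length; normalizing makes the diagonal exactly 1 and bounds every
    entry by 1 (cosine similarity).
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    norms = np.linalg.norm(centroids, axis=1)
    if (norms == 0).any():
        raise ValueError("zero centroid has no direction")
    U = centroids / norms[:, None]
    D = U @ U.T
    np.fill_diagonal(D, 1.0)
    return np.clip(D, -1.0, 1.0)


def collect_temporal_components(
    solution: ClusterSolution,
    pop: SynergyPopulation,
    synergy_sets: list[SynergySet],
) -> list[CentroidProfile]:
    """Route every member synergy's temporal component to its centroid.

    Each population row is traced through its provenance to the C row of
    its SynergySet; the per-repetition phase-normalized curves were already
    averaged per synergy, so each member contributes exactly one curve.
    Shares are assignment counts as percentages of the population.
    """
    if not pop.provenance:
        raise ValueError("population has no provenance; cannot trace temporals")
    by_key = {(ss.subject_id, ss.grasp_id): ss for ss in synergy_sets}
    curves: list[np.ndarray] = []
    for subject, grasp, j in pop.provenance:
        key = (subject, grasp)
        if key not in by_key:
            raise ValueError(f"orphan synergy: no SynergySet for {key}")
        curves.append(by_key[key].mean_temporal_components()[j])

    M = pop.size
    profiles: list[CentroidProfile] = []
    for c in range(solution.k):
        members = np.flatnonzero(solution.assignments == c)
        member_curves = [curves[i] for i in members]
        mean_curve = (
            np.mean(member_curves, axis=0)
            if member_curves
            else np.zeros_like(curves[0])
        )
        profiles.append(
            CentroidProfile(
                centroid=solution.centroids[c],
                share=100.0 * len(members) / M,
                mean_temporal=mean_curve,
                member_temporals=member_curves,
            )
        )
    return profiles


def temporal_correlation_matrix(profiles: list[CentroidProfile]) -> np.ndarray:
    """Pearson correlation matrix of the centroids' mean temporal components.

    A constant curve has no defined correlation; its entries are NaN and a
    warning is raised rather than an error, so one degenerate centroid does
    not abort the characterization.
    """
    curves = np.asarray([p.mean_temporal for p in profiles])
    k = curves.shape[0]
    sd = curves.std(axis=1)
    out = np.full((k, k), np.nan)
    ok = sd > 0
    if (~ok).any():
        import warnings

        warnings.warn(
            f"{int((~ok).sum())} constant mean temporal component(s); "
            "correlations set to NaN",
            stacklevel=2,
        )
    if ok.any():
        sub = np.corrcoef(curves[ok])
        out[np.ix_(ok, ok)] = np.atleast_2d(sub)
    for i in range(k):
        if ok[i]:
            out[i, i] = 1.0
    return out


@dataclass
class MatchedGrasp:
    """Cross-subject matched synergies for one grasp.

    Slot s holds the mean spatial synergy and the cumulated (subject-
    averaged) mean temporal component of all subjects' synergies matched to
    reference slot s. ``assignments`` maps subject_id to the slot index of
    each of its synergies, in input order.
    """

    grasp_id: int
    slot_spatial: np.ndarray  # (n_slots, channels)
    slot_temporal: np.ndarray  # (n_slots, n_phase)
    assignments: dict[str, list[int]]
    reference_subject: str


def _best_slot_permutation(
    slot_curves: list[np.ndarray], curves: np.ndarray
) -> tuple[int, ...]:
    """Exhaustive injective assignment of curves to slots maximizing total r."""
    n_slots, n_syn = len(slot_curves), curves.shape[0]
    best_total, best_perm = -np.inf, None
    for perm in permutations(range(n_slots), n_syn):
        total = 0.0
        for syn, slot in enumerate(perm):
            a, b = curves[syn], slot_curves[slot]
            if a.std() > 0 and b.std() > 0:
                total += float(np.corrcoef(a, b)[0, 1])
        if total > best_total:
            best_total, best_perm = total, perm
    return best_perm


def match_within_grasp(
    synergy_sets: list[SynergySet], log: list[str] | None = None
) -> MatchedGrasp:
    """Match synergies across subjects for one grasp by temporal correlation.

    The first subject's synergy ordering defines the reference slots. Every
    other subject's synergies are assigned to slots by maximizing the total
    Pearson correlation of temporal components over all injective slot
    assignments (exhaustive; module counts are ≤ 3). A subject with more
    synergies than there are slots opens new slots for the leftovers.
    """
    sets = [ss for ss in synergy_sets if ss.N > 0]
    skipped = [ss for ss in synergy_sets if ss.N == 0]
    if log is not None:
        for ss in skipped:
            log.append(f"subject {ss.subject_id}: no synergies, skipped")
    if len(sets) < 2:
        raise ValueError("need ≥ 2 subjects with extracted synergies to match")
    grasp_id = sets[0].grasp_id

    ref = sets[0]
    slot_curves = [c.copy() for c in ref.mean_temporal_components()]
    slot_spatials: list[list[np.ndarray]] = [[ref.W[:, j]] for j in range(ref.N)]
    slot_temporals: list[list[np.ndarray]] = [[c] for c in slot_curves]
    assignments: dict[str, list[int]] = {ref.subject_id: list(range(ref.N))}

    for ss in sets[1:]:
        curves = ss.mean_temporal_components()
        n_syn = curves.shape[0]
        while n_syn > len(slot_curves):  # leftovers open new slots
            slot_curves.append(np.zeros_like(curves[0]))
            slot_spatials.append([])
            slot_temporals.append([])
        perm = _best_slot_permutation(slot_curves, curves)
        assignments[ss.subject_id] = list(perm)
        for syn, slot in enumerate(perm):
            slot_spatials[slot].append(ss.W[:, syn])
            slot_temporals[slot].append(curves[syn])
            if not np.any(slot_curves[slot]):
                slot_curves[slot] = curves[syn]

    n_phase = slot_curves[0].shape[0]
    n_chan = sets[0].W.shape[0]
    spatial = np.zeros((len(slot_spatials), n_chan))
    temporal = np.zeros((len(slot_temporals), n_phase))
    for s, (ws, cs) in enumerate(zip(slot_spatials, slot_temporals)):
        if ws:
            spatial[s] = np.mean(ws, axis=0)
            temporal[s] = np.mean(cs, axis=0)
    return MatchedGrasp(
        grasp_id=grasp_id,
        slot_spatial=spatial,
        slot_temporal=temporal,
        assignments=assignments,
        reference_subject=sets[0].subject_id,
    )
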