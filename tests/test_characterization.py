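"""Centroid dot products, temporal routing and cross-subject matching."""

from itertools import permutations

import numpy as np
import pytest

from emgsynergy.characterization import (
    centroid_dot_matrix,
    collect_temporal_components,
    match_within_grasp,
    temporal_correlation_matrix,
    CentroidProfile,
)
from emgsynergy.clustering import ClusterSolution, SynergyPopulation
from emgsynergy.extraction import SynergySet
from emgsynergy.synthetic import make_activation


def _make_set(W, C, subject, grasp, n_phase, n_reps=1):
    return SynergySet(
        W=np.asarray(W, dtype=float),
        C=np.asarray(C, dtype=float),
        N=np.asarray(W).shape[1],
        vaf_curve=np.array([0.95]),
        subject_id=subject,
        grasp_id=grasp,
        n_phase=n_phase,
        n_reps=n_reps,
    )


class TestCentroidDotMatrix:
    def test_identical_centroids(self):
        c = np.tile([1.0, 2.0, 2.0], (3, 1))
        D = centroid_dot_matrix(c)
        np.testing.assert_allclose(D, 1.0)

    def test_orthogonal_centroids(self):
        D = centroid_dot_matrix(np.eye(4))
        np.testing.assert_allclose(D, np.eye(4))

    def test_symmetric_unit_diagonal_nonnegative(self, rng):
        c = rng.random((5, 12))
        D = centroid_dot_matrix(c)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 1.0)
        assert D.min() >= 0  # nonnegative synergies → nonnegative cosines
        assert D.max() <= 1.0

    def test_zero_centroid_rejected(self):
        with pytest.raises(ValueError):
            centroid_dot_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestCollectTemporalComponents:
    def _fixture(self, rng):
        n_phase = 50
        a = make_activation("monophasic", n_phase)
        b = make_activation("biphasic", n_phase)
        sets = [
            _make_set(rng.random((4, 1)), a[None, :], "s1", 1, n_phase),
            _make_set(rng.random((4, 1)), b[None, :], "s2", 1, n_phase),
        ]
        pop = SynergyPopulation(
            vectors=np.vstack([s.W[:, 0] for s in sets]),
            provenance=[("s1", 1, 0), ("s2", 1, 0)],
        )
        return sets, pop, a, b

    def test_mean_of_two_members(self, rng):
        sets, pop, a, b = self._fixture(rng)
        sol = ClusterSolution(
            k=1,
            centroids=pop.vectors.mean(axis=0, keepdims=True),
            assignments=np.zeros(2, dtype=int),
            med=0.1,
        )
        (profile,) = collect_temporal_components(sol, pop, sets)
        np.testing.assert_allclose(profile.mean_temporal, (a + b) / 2)
        assert profile.share == pytest.approx(100.0)

    def test_shares_from_assignment_counts(self, rng):
        n_phase = 20
        sets = [
            _make_set(rng.random((4, 1)), rng.random((1, n_phase)), f"s{i}", 1, n_phase)
            for i in range(10)
        ]
        pop = SynergyPopulation(
            vectors=np.vstack([s.W[:, 0] for s in sets]),
            provenance=[(f"s{i}", 1, 0) for i in range(10)],
        )
        assignments = np.array([0] * 5 + [1] * 3 + [2] * 2)
        sol = ClusterSolution(
            k=3, centroids=rng.random((3, 4)), assignments=assignments, med=0.1
        )
        profiles = collect_temporal_components(sol, pop, sets)
        assert [p.share for p in profiles] == [50.0, 30.0, 20.0]
        assert sum(p.share for p in profiles) == pytest.approx(100.0, abs=1e-9)

    def test_monophasic_cluster_has_single_peak(self, rng):
        # centroids dominated by monophasic members keep a single-peaked
        # mean temporal component (peak-count oracle on generator shapes)
        n_phase = 100
        curves = [
            make_activation("monophasic", n_phase, jitter=0.02, seed=i)
            for i in range(8)
        ]
        sets = [
            _make_set(rng.random((4, 1)), c[None, :], f"s{i}", 1, n_phase)
            for i, c in enumerate(curves)
        ]
        pop = SynergyPopulation(
            vectors=np.vstack([s.W[:, 0] for s in sets]),
            provenance=[(f"s{i}", 1, 0) for i in range(8)],
        )
        sol = ClusterSolution(
            k=1,
            centroids=pop.vectors.mean(axis=0, keepdims=True),
            assignments=np.zeros(8, dtype=int),
            med=0.1,
        )
        (profile,) = collect_temporal_components(sol, pop, sets)
        m = profile.mean_temporal
        interior = (m[1:-1] > m[:-2]) & (m[1:-1] > m[2:])
        peaks = np.flatnonzero(interior & (m[1:-1] > 0.1 * m.max()))
        assert len(peaks) == 1

    def test_orphan_synergy_rejected(self, rng):
        sets, pop, _, _ = self._fixture(rng)
        pop.provenance[1] = ("missing", 9, 0)
        sol = ClusterSolution(
            k=1,
            centroids=pop.vectors.mean(axis=0, keepdims=True),
            assignments=np.zeros(2, dtype=int),
            med=0.1,
        )
        with pytest.raises(ValueError, match="orphan"):
            collect_temporal_components(sol, pop, sets)


class TestTemporalCorrelationMatrix:
    def _profiles(self, curves):
        return [
            CentroidProfile(
                centroid=np.ones(3), share=100.0 / len(curves), mean_temporal=c
            )
            for c in curves
        ]

    def test_self_correlation(self, rng):
        c = rng.random(40)
        M = temporal_correlation_matrix(self._profiles([c, c.copy()]))
        np.testing.assert_allclose(M, 1.0)

    def test_vertical_mirror_anticorrelates(self, rng):
        c = rng.random(40)
        M = temporal_correlation_matrix(self._profiles([c, c.max() - c]))
        assert M[0, 1] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        curves = [rng.random(30) for _ in range(4)]
        M = temporal_correlation_matrix(self._profiles(curves))
        np.testing.assert_allclose(M, M.T)
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert np.nanmax(np.abs(M)) <= 1.0 + 1e-12

    def test_constant_curve_flagged_nan(self, rng):
        curves = [rng.random(30), np.full(30, 2.0)]
        with pytest.warns(UserWarning, match="constant"):
            M = temporal_correlation_matrix(self._profiles(curves))
        assert np.isnan(M[0, 1]) and np.isnan(M[1, 1])
        assert M[0, 0] == 1.0


class TestMatchWithinGrasp:
    def _subject_sets(self, rng, n_phase=60):
        a = make_activation("monophasic", n_phase)
        b = make_activation("biphasic", n_phase)
        W1 = np.abs(rng.random((6, 2))) + 0.1
        C1 = np.vstack([a, b])
        # subject 2 has the same synergies in swapped order
        s1 = _make_set(W1, C1, "s1", 3, n_phase)
        s2 = _make_set(W1[:, ::-1], C1[::-1], "s2", 3, n_phase)
        return s1, s2, a, b

    def test_swapped_order_unswapped(self, rng):
        s1, s2, _, _ = self._subject_sets(rng)
        matched = match_within_grasp([s1, s2])
        assert matched.assignments["s1"] == [0, 1]
        assert matched.assignments["s2"] == [1, 0]  # inverse of the swap
        np.testing.assert_allclose(matched.slot_spatial, s1.W.T)

    def test_slot_temporal_structure(self, rng):
        # slot 1 (grasp/hold) peaks in the middle third; slot 2
        # (pre-shaping/release) has ≥ 2 local maxima
        s1, s2, a, b = self._subject_sets(rng)
        matched = match_within_grasp([s1, s2])
        n = matched.slot_temporal.shape[1]
        assert n // 3 <= matched.slot_temporal[0].argmax() < 2 * n // 3
        m = matched.slot_temporal[1]
        interior = (m[1:-1] > m[:-2]) & (m[1:-1] > m[2:])
        assert interior.sum() >= 2

    def test_invariant_to_member_ordering(self, rng):
        n_phase = 60
        curves = [
            make_activation("monophasic", n_phase),
            make_activation("biphasic", n_phase),
            make_activation("biphasic", n_phase, balance=(0.2, 1.0)),
        ]
        ref = _make_set(
            np.abs(rng.random((5, 3))) + 0.1, np.vstack(curves), "ref", 1, n_phase
        )
        W2 = np.abs(rng.random((5, 3))) + 0.1
        C2 = np.vstack(
            [c * rng.uniform(0.8, 1.2) for c in curves]
        )
        results = []
        for perm in permutations(range(3)):
            other = _make_set(W2[:, perm], C2[list(perm)], "s2", 1, n_phase)
            matched = match_within_grasp([ref, other])
            results.append(matched.slot_spatial.copy())
        for r in results[1:]:
            np.testing.assert_allclose(r, results[0], atol=1e-12)

    def test_exhaustive_at_least_as_good_as_greedy(self, rng):
        # brute-force permutation oracle: the chosen assignment's total
        # correlation is >= any greedy assignment's total
        n_phase = 40
        ref_curves = rng.random((3, n_phase))
        other_curves = rng.random((3, n_phase))
        ref = _make_set(rng.random((5, 3)), ref_curves, "r", 1, n_phase)
        other = _make_set(rng.random((5, 3)), other_curves, "o", 1, n_phase)
        matched = match_within_grasp([ref, other])
        perm = matched.assignments["o"]

        def total(p):
            return sum(
                np.corrcoef(other_curves[i], ref_curves[p[i]])[0, 1]
                for i in range(3)
            )

        assert total(perm) == pytest.approx(
            max(total(p) for p in permutations(range(3))), abs=1e-12
        )

    def test_single_subject_rejected(self, rng):
        s = _make_set(rng.random((4, 1)), rng.random((1, 20)), "s1", 1, 20)
        with pytest.raises(ValueError, match="2 subjects"):
            match_within_grasp([s])
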