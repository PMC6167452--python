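"""Spatial-synergy extraction by non-negative matrix factorization.

A pooled envelope matrix V (channels × time) is factorized as V ≈ W·C with
W, C ≥ 0: the columns of W are time-invariant spatial synergies (muscle
co-activation weight vectors) and the rows of C their time-varying
activation commands. Factorization uses Lee–Seung multiplicative updates
for the squared Frobenius loss, restarted from many random initializations
to escape local minima; the restart with the highest variance accounted
for (VAF) represents each order. The model order N is the smallest r whose
VAF reaches 90 %, extended while each additional synergy still adds at
least 5 % VAF.

VAF is uncentered: VAF = 1 − ‖V − W·C‖²_F / ‖V‖²_F. Envelopes are
nonnegative, so total signal energy (not mean-centered variance) is the
convention here; a mean-centered definition would select different orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import Trial

_EPS = 1e-12


class InputError(ValueError):
    """The matrix to factorize violates a precondition."""


@dataclass
class SynergySet:
    """Result of extraction on one pooled subject×grasp matrix.

    W has shape (channels, N) with unit-norm columns; C has shape
    (N, n_reps·n_phase) in envelope amplitude units. ``vaf_curve[r-1]`` is
    the best-of-restarts VAF at order r for every order that was computed.
    """

    W: np.ndarray
    C: np.ndarray
    N: int
    vaf_curve: np.ndarray
    subject_id: str = ""
    grasp_id: int = 0
    seed: int = 0
    n_phase: int = 0
    n_reps: int = 1
    threshold_reached: bool = True

    def mean_temporal_components(self) -> np.ndarray:
        """Per-synergy temporal component averaged across repetitions.

        Returns an (N, n_phase) array: each pooled C row is split back into
        its per-repetition phase-normalized curves, which are averaged so
        each synergy contributes a single curve downstream.
        """
        n_phase = self.n_phase or self.C.shape[1]
        reps = self.C.shape[1] // n_phase
        return self.C[:, : reps * n_phase].reshape(self.N, reps, n_phase).mean(axis=1)


def vaf(V: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Uncentered variance accounted for by the reconstruction W·C."""
    V = np.asarray(V, dtype=float)
    total = float(np.sum(V * V))
    if total == 0.0:
        raise InputError("VAF undefined for an all-zero matrix")
    resid = V - W @ C
    return 1.0 - float(np.sum(resid * resid)) / total


def _mu_nmf(
    V: np.ndarray,
    r: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    trace: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update run from a random initialization."""
    n, m = V.shape
    scale = np.sqrt(V.mean() / r) if V.mean() > 0 else 1.0
    # uniform in (0, 1]: avoids exact zeros that multiplicative updates
    # can never leave
    W = (1.0 - rng.random((n, r))) * scale
    C = (1.0 - rng.random((r, m))) * scale
    total = float(np.sum(V * V))
    prev = np.inf
    for _ in range(max_iter):
        C *= (W.T @ V) / (W.T @ W @ C + _EPS)
        W *= (V @ C.T) / (W @ (C @ C.T) + _EPS)
        resid = V - W @ C
        err = float(np.sum(resid * resid))
        if trace is not None:
            trace.append(err)
        if prev - err < tol * total:
            prev = err
            break
        prev = err
    return W, C, 1.0 - prev / total


def _normalize_columns(
    W: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescale W columns to unit norm, absorbing the scale into C rows."""
    norms = np.linalg.norm(W, axis=0)
    dead = norms < _EPS
    safe = np.where(dead, 1.0, norms)
    return W / safe, C * safe[:, None], dead


def nmf_factorize(
    V: np.ndarray,
    r: int,
    n_reps: int = 1000,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts NMF of a nonnegative channels×time matrix.

    Runs ``n_reps`` multiplicative-update factorizations from independent
    random initializations (per-restart seeds derived from ``seed`` by a
    counter-based scheme, so any single restart is reproducible in
    isolation) and keeps the one with the highest VAF. Restarts that
    produce a dead (all-zero) synergy column are discarded in favor of the
    next best. W is returned with unit-norm columns, scale absorbed in C.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise InputError("V must be 2-D (channels × time)")
    if (V < 0).any():
        raise InputError("V must be elementwise nonnegative")
    if np.isnan(V).all(axis=1).any():
        raise InputError("V contains an all-NaN row")
    if not 1 <= r <= min(V.shape):
        raise ValueError(f"order r={r} out of range 1..{min(V.shape)}")

    root = np.random.SeedSequence(seed)
    candidates: list[tuple[float, np.ndarray, np.ndarray, bool]] = []
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        W, C, v = _mu_nmf(V, r, rng, max_iter, tol)
        Wn, Cn, dead = _normalize_columns(W, C)
        candidates.append((v, Wn, Cn, bool(dead.any())))
    candidates.sort(key=lambda t: t[0], reverse=True)
    alive = [c for c in candidates if not c[3]]
    v, W, C, _ = alive[0] if alive else candidates[0]
    if not alive:
        warnings.warn(
            f"all {n_reps} restarts at order {r} produced a dead synergy "
            "column; returning the best anyway",
            stacklevel=2,
        )
    return W, np.clip(C, 0.0, None), v


def select_order(
    V: np.ndarray,
    r_max: int = 12,
    vaf_threshold: float = 0.90,
    increment: float = 0.05,
    n_reps: int = 1000,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    full_curve: bool = False,
) -> SynergySet:
    """Choose the model order by the 90 % VAF / 5 % increment rule.

    Let r₀ be the smallest order whose VAF reaches ``vaf_threshold``. The
    selected order N extends past r₀ only while each further synergy adds
    at least ``increment`` of VAF. Factorizations are computed for
    increasing r and stop one order past the decision point unless
    ``full_curve`` requests the whole curve up to ``r_max``. If the
    threshold is never reached, N = r_max and the result is flagged.
    """
    if r_max < 1:
        raise ValueError("r_max must be ≥ 1")
    r_max = min(r_max, min(np.asarray(V).shape))
    curve: list[float] = []
    results: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    r0 = None
    N = None
    for r in range(1, r_max + 1):
        W, C, v = nmf_factorize(
            V, r, n_reps=n_reps, max_iter=max_iter, tol=tol, seed=seed + r
        )
        curve.append(v)
        results[r] = (W, C)
        if r0 is None and v >= vaf_threshold:
            r0 = r
            N = r
        elif r0 is not None and N == r - 1:
            if v - curve[r - 2] >= increment:
                N = r
            elif not full_curve:
                break
    reached = r0 is not None
    if not reached:
        warnings.warn(
            f"VAF threshold {vaf_threshold} not reached by r_max={r_max}; "
            "returning N=r_max",
            stacklevel=2,
        )
        N = r_max
    W, C = results[N]
    return SynergySet(
        W=W,
        C=C,
        N=N,
        vaf_curve=np.asarray(curve),
        seed=seed,
        threshold_reached=reached,
    )


def extract_dataset(
    trials: list[Trial],
    r_max: int = 12,
    vaf_threshold: float = 0.90,
    increment: float = 0.05,
    n_reps: int = 1000,
    max_iter: int = 500,
    tol: float = 1e-6,
    master_seed: int = 0,
    log: list[str] | None = None,
) -> list[SynergySet]:
    """Run order selection on every subject×grasp pooled matrix.

    Phase-normalized envelope trials are grouped by (subject, grasp), the
    repetitions concatenated horizontally into one channels×time matrix,
    and :func:`select_order` applied per group. Groups without usable
    trials are skipped with a log entry.
    """
    groups: dict[tuple[str, int], list[Trial]] = {}
    for t in trials:
        groups.setdefault((t.subject_id, t.grasp_id), []).append(t)

    out: list[SynergySet] = []
    root = np.random.SeedSequence(master_seed)
    keys = sorted(groups)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(len(keys))]
    for (subject, grasp), seed in zip(keys, seeds):
        members = sorted(groups[(subject, grasp)], key=lambda t: t.repetition)
        members = [t for t in members if t.env.size and t.env.sum() > 0]
        if not members:
            if log is not None:
                log.append(f"group {subject}×{grasp}: no usable trials, skipped")
            continue
        V = np.hstack([t.env for t in members])
        ss = select_order(
            V,
            r_max=r_max,
            vaf_threshold=vaf_threshold,
            increment=increment,
            n_reps=n_reps,
            max_iter=max_iter,
            tol=tol,
            seed=seed,
        )
        ss.subject_id = subject
        ss.grasp_id = grasp
        ss.n_phase = members[0].n_points
        ss.n_reps = len(members)
        out.append(ss)
    return out
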