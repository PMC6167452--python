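"""Synthetic multi-subject, multi-grasp sEMG with known ground truth.

The generator runs the synergy model forwards: a small set of prototype
spatial synergies (sparse nonnegative unit vectors over 12 channels) plays
the role of the "true" cluster centroids; each grasp recruits 1-3 of them;
each simulated subject perturbs the recruited prototypes slightly; each
repetition drives them with jittered activation profiles — a monophasic
bell centered mid-movement for the grasp/hold module, biphasic
(pre-shaping + release) bumps for the accessory modules — and additive
truncated-Gaussian noise corrupts the resulting envelopes. Because the
prototypes, weights and activations are all known, every pipeline stage
(order selection, clustering order, centroid recovery, temporal shapes)
can be checked against ground truth. Raw 2 kHz signals are synthesized on
top by amplitude-modulating a broadband carrier, which lets the filter
chain be tested end-to-end.

What this emulates and what it does not: the generator reproduces the
low-dimensional structure, repetition/subject variability and envelope
statistics that the analysis consumes, not the physiology underneath — no
motor-unit action potentials, electrode cross-talk, or fatigue drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EMGRecording
from .preprocessing import Trial

#: per-grasp module-count distribution: most grasps decompose into one or
#: two modules, a few into three
N_SYN_CHOICES = (1, 2, 3)
N_SYN_WEIGHTS = (0.35, 0.55, 0.10)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    prototypes: np.ndarray  # (n_prototypes, channels), unit rows
    grasp_prototypes: dict[int, list[int]] = field(default_factory=dict)
    profile_kinds: dict[int, list[str]] = field(default_factory=dict)
    W_true: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    C_true: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0


def make_prototypes(
    n_channels: int = 12,
    n_prototypes: int = 10,
    seed: int = 0,
    max_cosine: float = 0.9,
    active_range: tuple[int, int] = (3, 6),
    max_tries: int = 10_000,
) -> np.ndarray:
    """Sparse nonnegative unit prototype synergies, pairwise cosine-bounded.

    Each prototype activates 3-6 of the channels with positive weights;
    candidates too similar (cosine > ``max_cosine``) to an accepted
    prototype are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    protos: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(protos) == n_prototypes:
            break
        n_active = rng.integers(active_range[0], active_range[1] + 1)
        chans = rng.choice(n_channels, size=n_active, replace=False)
        v = np.zeros(n_channels)
        v[chans] = rng.uniform(0.3, 1.0, size=n_active)
        v /= np.linalg.norm(v)
        if all(float(v @ p) <= max_cosine for p in protos):
            protos.append(v)
    if len(protos) < n_prototypes:
        raise RuntimeError(
            f"could not draw {n_prototypes} prototypes with pairwise cosine "
            f"≤ {max_cosine} in {max_tries} tries; reduce n_prototypes"
        )
    return np.asarray(protos)


def make_activation(
    kind: str,
    n_phase: int,
    amplitude: float = 1.0,
    jitter: float = 0.0,
    seed: int | np.random.Generator = 0,
    balance: tuple[float, float] = (1.0, 0.8),
) -> np.ndarray:
    """One activation profile over the 0-100 % phase axis.

    ``monophasic`` is a Gaussian bump centered at 50 % phase (sd 15 % of
    phase) — the grasp/hold pattern. ``biphasic`` is the sum of two bumps
    near 15 % and 85 % — pre-shaping and release — with relative heights
    ``balance``; skewing the balance differentiates a pre-shaping-dominant
    module from a release-dominant one. ``jitter`` shifts bump centers by
    a zero-mean Gaussian of that sd (in phase fraction).
    """
    if n_phase < 10:
        raise ValueError("n_phase must be ≥ 10")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phi = np.linspace(0.0, 1.0, n_phase)

    def bump(center: float, sd: float, amp: float) -> np.ndarray:
        c = center + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        return amp * np.exp(-((phi - c) ** 2) / (2 * sd**2))

    if kind == "monophasic":
        curve = bump(0.50, 0.15, amplitude)
    elif kind == "biphasic":
        curve = bump(0.15, 0.08, balance[0] * amplitude) + bump(
            0.85, 0.08, balance[1] * amplitude
        )
    else:
        raise ValueError(f"unknown activation kind {kind!r}")
    return np.clip(curve, 0.0, None)


def _perturb_prototype(
    proto: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Nonnegative perturbation of a prototype, renormalized to unit norm."""
    w = proto + np.abs(rng.normal(0.0, sd, size=proto.shape))
    return w / np.linalg.norm(w)


def synthesize_group(
    prototypes: np.ndarray,
    n_syn: int,
    n_reps: int = 6,
    subject_variability: float = 0.01,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_phase: int = 100,
    proto_indices: list[int] | None = None,
    subject_id: str = "S1",
    grasp_id: int = 1,
    jitter: float = 0.02,
) -> tuple[list[Trial], np.ndarray, np.ndarray]:
    """Forward-model envelope trials for one subject×grasp group.

    Returns ``(trials, W_true, C_true)`` where W_true is (channels, n_syn)
    with unit columns and C_true is (n_syn, n_reps·n_phase), the
    concatenated per-repetition activations. The first recruited module is
    monophasic (grasp/hold); accessory modules are biphasic at 80 %
    amplitude, the second pre-shaping-dominant and the third
    release-dominant so that three-module groups stay identifiable (two
    modules with proportional activations would collapse into one).
    Envelopes are W_true·C_true plus additive Gaussian noise, clipped at
    zero.
    """
    if n_syn > prototypes.shape[0]:
        raise ValueError("n_syn exceeds available prototypes")
    rng = np.random.default_rng(seed)
    if proto_indices is None:
        proto_indices = list(
            rng.choice(prototypes.shape[0], size=n_syn, replace=False)
        )
    W_true = np.column_stack(
        [
            _perturb_prototype(prototypes[i], subject_variability, rng)
            for i in proto_indices
        ]
    )
    kinds = ["monophasic"] + ["biphasic"] * (n_syn - 1)
    balances = [(1.0, 0.8), (1.0, 0.2), (0.2, 1.0)][:n_syn]
    trials: list[Trial] = []
    C_cols: list[np.ndarray] = []
    for rep in range(1, n_reps + 1):
        C_rep = np.vstack(
            [
                make_activation(
                    kind,
                    n_phase,
                    amplitude=1.0,
                    jitter=jitter,
                    seed=rng,
                    balance=bal,
                )
                for kind, bal in zip(kinds, balances)
            ]
        )
        C_rep[1:] *= 0.8  # accessory modules are minor
        V = W_true @ C_rep
        if noise_sd > 0:
            V = V + rng.normal(0.0, noise_sd, size=V.shape)
        V = np.clip(V, 0.0, None)
        trials.append(
            Trial(
                env=V,
                grasp_id=grasp_id,
                repetition=rep,
                subject_id=subject_id,
                phase_axis=np.linspace(0.0, 100.0, n_phase),
            )
        )
        C_cols.append(C_rep)
    return trials, W_true, np.hstack(C_cols)


def synthesize_dataset(
    n_subjects: int = 28,
    n_grasps: int = 20,
    n_channels: int = 12,
    n_prototypes: int = 10,
    n_reps: int = 6,
    n_phase: int = 100,
    subject_variability: float = 0.01,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[Trial], GroundTruth]:
    """A full multi-subject study with shared per-grasp synergy structure.

    Each grasp draws its module count (1-3, weighted toward 2) and its
    prototype recruitment once; subjects share that structure but perturb
    the prototype weights, so the population of extracted synergies
    clusters around the prototypes — a well-defined true clustering order.
    """
    root = np.random.default_rng(seed)
    prototypes = make_prototypes(
        n_channels=n_channels,
        n_prototypes=n_prototypes,
        seed=int(root.integers(2**31)),
    )
    gt = GroundTruth(prototypes=prototypes, noise_sd=noise_sd, seed=seed)
    for g in range(1, n_grasps + 1):
        n_syn = int(root.choice(N_SYN_CHOICES, p=N_SYN_WEIGHTS))
        idx = list(root.choice(n_prototypes, size=n_syn, replace=False))
        gt.grasp_prototypes[g] = [int(i) for i in idx]
        gt.profile_kinds[g] = ["monophasic"] + ["biphasic"] * (n_syn - 1)

    trials: list[Trial] = []
    for s in range(1, n_subjects + 1):
        subject_id = f"S{s:02d}"
        for g in range(1, n_grasps + 1):
            idx = gt.grasp_prototypes[g]
            t, W, C = synthesize_group(
                prototypes,
                n_syn=len(idx),
                n_reps=n_reps,
                subject_variability=subject_variability,
                noise_sd=noise_sd,
                seed=int(root.integers(2**31)),
                n_phase=n_phase,
                proto_indices=idx,
                subject_id=subject_id,
                grasp_id=g,
            )
            gt.W_true[(subject_id, g)] = W
            gt.C_true[(subject_id, g)] = C
            trials.extend(t)
    return trials, gt


def synthesize_raw(
    trials: list[Trial],
    carrier_fs: float = 2000.0,
    seed: int = 0,
    movement_s: float = 5.0,
    rest_s: float = 3.0,
    carrier_band: tuple[float, float] = (60.0, 450.0),
    subject_id: str = "",
) -> EMGRecording:
    """Lay envelope trials into a labeled 2 kHz raw-signal timeline.

    Each trial's envelope is upsampled onto a ``movement_s``-long window
    and multiplies a zero-mean broadband Gaussian carrier band-passed to
    ``carrier_band``; movements are separated by ``rest_s`` of rest
    (label 0). Running the preprocessing chain on the output recovers
    envelopes proportional to the inputs.
    """
    rng = np.random.default_rng(seed)
    n_move = int(round(movement_s * carrier_fs))
    n_rest = int(round(rest_s * carrier_fs))
    n_channels = trials[0].n_channels if trials else 0
    total = n_rest + len(trials) * (n_move + n_rest)

    env_t = np.zeros((total, n_channels))
    labels = np.zeros(total, dtype=int)
    pos = n_rest
    for t in trials:
        src = np.linspace(0.0, 1.0, t.n_points)
        dst = np.linspace(0.0, 1.0, n_move)
        for c in range(n_channels):
            env_t[pos : pos + n_move, c] = np.interp(dst, src, t.env[c])
        labels[pos : pos + n_move] = t.grasp_id
        pos += n_move + n_rest

    sos = sps.butter(4, carrier_band, btype="bandpass", fs=carrier_fs, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal(env_t.shape), axis=0)
    raw = env_t * carrier
    return EMGRecording(
        emg=raw,
        fs=carrier_fs,
        labels=labels,
        subject_id=subject_id or (trials[0].subject_id if trials else ""),
    )
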