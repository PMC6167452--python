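"""sEMG preprocessing: filtering, envelope, segmentation, phase normalization.

The chain mirrors standard synergy-extraction practice: a zero-phase 50 Hz
high-pass (7th-order Butterworth, forward-backward) removes motion
artifacts; the signal is full-wave rectified; the magnitude of the analytic
signal of the rectified trace gives an instantaneous amplitude; a causal
(single-pass) 10 Hz Butterworth low-pass smooths it into an envelope.
Movement segments are cut out of the label stream and linearly resampled
onto a common 0-100 % phase axis so repetitions and subjects can be pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import EMGRecording


class ParameterError(ValueError):
    """A filter or segmentation parameter is out of its valid range."""


@dataclass
class EnvelopeMatrix:
    """Nonnegative amplitude envelopes aligned with a label stream.

    ``env`` has shape (samples, channels); ``fs`` is the post-decimation
    sampling rate in Hz.
    """

    env: np.ndarray
    fs: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        self.labels = np.asarray(self.labels).ravel().astype(int)
        if self.env.shape[0] != self.labels.shape[0]:
            raise ValueError("env rows and labels must be aligned")
        if (self.env < 0).any():
            raise ValueError("envelope entries must be nonnegative")


@dataclass
class Trial:
    """One movement segment for one repetition of one grasp.

    ``env`` has shape (channels, n_points). Before phase normalization the
    segment has its native variable length and ``phase_axis`` is None;
    after :func:`normalize_phase` all trials share a fixed length and a
    0-100 % phase axis.
    """

    env: np.ndarray
    grasp_id: int
    repetition: int
    subject_id: str = ""
    phase_axis: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.env.shape[0]

    @property
    def n_points(self) -> int:
        return self.env.shape[1]


def highpass_filter(
    x: np.ndarray, fs: float, cutoff: float = 50.0, order: int = 7
) -> np.ndarray:
    """Zero-phase Butterworth high-pass, applied per channel.

    Forward-backward filtering squares the magnitude response, so the
    effective gain at frequency f is |H(f)|² with |H| the one-pass
    Butterworth magnitude; the phase response is identically zero.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if cutoff >= fs / 2:
        raise ParameterError(
            f"high-pass cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz"
        )
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite samples")
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def envelope(
    x: np.ndarray,
    fs: float,
    lp_cutoff: float = 10.0,
    order: int = 7,
    out_fs: float | None = 100.0,
    labels: np.ndarray | None = None,
) -> EnvelopeMatrix:
    """Rectify, take the analytic-signal magnitude, low-pass, decimate.

    The low-pass is causal (single forward pass); the tiny negative ripple
    a Butterworth can introduce is clipped to zero so the result satisfies
    the nonnegativity NMF requires. When ``out_fs`` is given and lower than
    ``fs`` the envelope (10 Hz-limited by construction) is subsampled onto
    the coarser grid together with its labels.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels).ravel().astype(int)
    if out_fs is None or out_fs >= fs:
        out_fs = fs
    if lp_cutoff >= out_fs / 2:
        raise ParameterError(
            f"low-pass cutoff {lp_cutoff} Hz must be below the output "
            f"Nyquist {out_fs / 2} Hz"
        )
    rect = np.abs(x)
    analytic = np.abs(sps.hilbert(rect, axis=0))
    sos = sps.butter(order, lp_cutoff, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfilt(sos, analytic, axis=0)
    env = np.clip(env, 0.0, None)
    if out_fs < fs:
        n_out = int(np.floor(n * out_fs / fs))
        idx = np.floor(np.arange(n_out) * fs / out_fs).astype(int)
        env = env[idx]
        labels = labels[idx]
    return EnvelopeMatrix(env=env, fs=out_fs, labels=labels)


def _label_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of constant label: list of (value, start, stop)."""
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]

def segment_trials(
    env: EnvelopeMatrix,
    grasp_ids: set[int] | None = None,
    subject_id: str = "",
    pad_ms: float = 0.0,
) -> list[Trial]:
    """Cut one variable-length Trial per run of a constant nonzero label.

    Repetition indices are assigned in temporal order within each grasp.
    ``pad_ms`` extends each segment symmetrically into the surrounding rest
    (clipped at the recording edges) for sensitivity analyses.
    """
    pad = int(round(pad_ms / 1000.0 * env.fs))
    trials: list[Trial] = []
    rep_count: dict[int, int] = {}
    for value, start, stop in _label_runs(env.labels):
        if value == 0 or (grasp_ids is not None and value not in grasp_ids):
            continue
        a = max(0, start - pad)
        b = min(env.env.shape[0], stop + pad)
        rep_count[value] = rep_count.get(value, 0) + 1
        trials.append(
            Trial(
                env=env.env[a:b].T.copy(),
                grasp_id=value,
                repetition=rep_count[value],
                subject_id=subject_id,
            )
        )
    return trials


def normalize_phase(trial: Trial, n_phase: int = 1000) -> Trial:
    """Linearly resample a segment onto ``n_phase`` equally spaced phase points.

    The phase axis spans 0-100 % of the segment; endpoint values are
    preserved exactly. Idempotent (up to float rounding) for segments
    already of length ``n_phase``.
    """
    if trial.n_points < 2:
        raise ValueError(
            f"segment of {trial.n_points} samples cannot be phase-normalized"
        )
    src = np.linspace(0.0, 1.0, trial.n_points)
    dst = np.linspace(0.0, 1.0, n_phase)
    out = np.empty((trial.n_channels, n_phase))
    for c in range(trial.n_channels):
        out[c] = np.interp(dst, src, trial.env[c])
    return Trial(
        env=out,
        grasp_id=trial.grasp_id,
        repetition=trial.repetition,
        subject_id=trial.subject_id,
        phase_axis=dst * 100.0,
    )


def flag_noisy_channels(
    env: EnvelopeMatrix, rms_multiple: float = 3.0
) -> list[int]:
    """Flag channels whose rest-period RMS is an outlier.

    A channel is flagged when its RMS over rest samples (label 0) exceeds
    ``rms_multiple`` times the median rest RMS across channels. Advisory
    only: nothing is dropped automatically, since removing channels changes
    the decomposition for the remaining ones.
    """
    rest = env.labels == 0
    data = env.env[rest] if rest.any() else env.env
    if data.shape[0] == 0:
        return []
    rms = np.sqrt(np.mean(data**2, axis=0))
    med = np.median(rms)
    if med == 0:
        return [int(i) for i in np.flatnonzero(rms > 0)]
    return [int(i) for i in np.flatnonzero(rms > rms_multiple * med)]


def preprocess_recording(
    rec: EMGRecording,
    hp_cutoff_hz: float = 50.0,
    hp_order: int = 7,
    lp_cutoff_hz: float = 10.0,
    lp_order: int = 7,
    envelope_out_fs: float = 100.0,
    n_phase: int = 1000,
    pad_ms: float = 0.0,
    grasp_ids: set[int] | None = None,
    exclude_channels: list[int] | None = None,
) -> list[Trial]:
    """Full chain: high-pass → envelope → segment → phase-normalize."""
    emg = rec.emg
    if exclude_channels:
        keep = [c for c in range(rec.n_channels) if c not in exclude_channels]
        emg = emg[:, keep]
    hp = highpass_filter(emg, rec.fs, cutoff=hp_cutoff_hz, order=hp_order)
    env = envelope(
        hp,
        rec.fs,
        lp_cutoff=lp_cutoff_hz,
        order=lp_order,
        out_fs=envelope_out_fs,
        labels=rec.labels,
    )
    raw_trials = segment_trials(
        env, grasp_ids=grasp_ids, subject_id=rec.subject_id, pad_ms=pad_ms
    )
    return [normalize_phase(t, n_phase=n_phase) for t in raw_trials]
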