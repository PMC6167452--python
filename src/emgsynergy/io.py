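"""Reading NinaPro-style MAT recordings and tab-delimited matrix I/O.

NinaPro distributions ship recordings as MATLAB files in either the classic
v5 binary layout or the HDF5-backed v7.3 layout; both are supported and
auto-detected. All pipeline result matrices are written as tab-delimited
UTF-8 text with a single header row and a row-label column, one file per
matrix, so every stage can be inspected and re-loaded with ordinary tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io


class FormatError(ValueError):
    """A recording file is missing a required field or is malformed."""


class DimensionError(ValueError):
    """Array shapes in a recording or matrix file are inconsistent."""


@dataclass
class EMGRecording:
    """Raw multichannel sEMG with a per-sample movement-label stream.

    Attributes
    ----------
    emg:
        Array of shape (samples, channels). Amplitude units are whatever the
        acquisition produced (volts for NinaPro); nonnegativity is not
        required at this stage.
    fs:
        Sampling rate in Hz (2000 for NinaPro DB2).
    labels:
        Integer vector of length samples; 0 marks rest, g > 0 marks grasp g.
    subject_id, exercise_id, channel_names:
        Provenance metadata.
    """

    emg: np.ndarray
    fs: float
    labels: np.ndarray
    subject_id: str = ""
    exercise_id: int = 0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.labels = np.asarray(self.labels).ravel().astype(int)
        if self.emg.ndim != 2:
            raise DimensionError(f"emg must be 2-D, got shape {self.emg.shape}")
        if self.emg.shape[0] != self.labels.shape[0]:
            raise DimensionError(
                f"emg has {self.emg.shape[0]} samples but labels has "
                f"{self.labels.shape[0]} entries"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if (self.labels < 0).any():
            raise ValueError("labels must be nonnegative integers")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise DimensionError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]


def _detect_dialect(path: Path) -> str:
    return "mat-v7.3" if h5py.is_hdf5(path) else "mat-v5"


def _load_mat_v5(path: Path) -> dict[str, np.ndarray]:
    raw = scipy.io.loadmat(path, squeeze_me=False)
    return {k: v for k, v in raw.items() if not k.startswith("__")}


def _load_mat_v73(path: Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        for key, ds in f.items():
            if isinstance(ds, h5py.Dataset):
                arr = np.asarray(ds)
                # MATLAB stores column-major; HDF5 exposes the transpose.
                if arr.ndim == 2:
                    arr = arr.T
                out[key] = arr
    return out


def read_ninapro_recording(
    path: str | Path,
    dialect: str = "auto",
    fs: float = 2000.0,
    emg_field: str = "emg",
    label_fields: tuple[str, ...] = ("restimulus", "stimulus"),
) -> EMGRecording:
    """Read one NinaPro-style MAT recording into an :class:`EMGRecording`.

    The refined movement-label stream (``restimulus``) is preferred; when a
    file carries only the raw cue stream (``stimulus``) that one is used
    with a warning, since cue timing lags the actual movement.

    Parameters
    ----------
    dialect:
        ``"mat-v5"``, ``"mat-v7.3"`` or ``"auto"`` (detected from the file
        header; v7.3 files are HDF5 containers).
    fs:
        Sampling rate to record; NinaPro DB2 is acquired at 2 kHz.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect == "mat-v5":
        fields = _load_mat_v5(path)
    elif dialect == "mat-v7.3":
        fields = _load_mat_v73(path)
    else:
        raise ValueError(f"unknown MAT dialect {dialect!r}")

    if emg_field not in fields:
        raise FormatError(f"{path.name}: missing sEMG field {emg_field!r}")
    emg = np.asarray(fields[emg_field], dtype=float)
    if emg.ndim != 2:
        raise DimensionError(f"{path.name}: sEMG field is not a 2-D matrix")

    labels = None
    for i, lf in enumerate(label_fields):
        if lf in fields:
            labels = np.asarray(fields[lf]).ravel()
            if i > 0:
                warnings.warn(
                    f"{path.name}: refined label field "
                    f"{label_fields[0]!r} absent, falling back to {lf!r}",
                    stacklevel=2,
                )
            break
    if labels is None:
        raise FormatError(
            f"{path.name}: missing label field (looked for {label_fields})"
        )
    if labels.shape[0] != emg.shape[0]:
        raise DimensionError(
            f"{path.name}: {emg.shape[0]} sEMG samples but "
            f"{labels.shape[0]} label samples"
        )

    subject = ""
    if "subject" in fields:
        subject = str(np.asarray(fields["subject"]).ravel()[0])
    exercise = 0
    if "exercise" in fields:
        exercise = int(np.asarray(fields["exercise"]).ravel()[0])
    return EMGRecording(
        emg=emg, fs=fs, labels=labels, subject_id=subject, exercise_id=exercise
    )


def write_matrix(
    path: str | Path,
    m: np.ndarray,
    row_names: list[str] | None = None,
    col_names: list[str] | None = None,
) -> Path:
    """Write a matrix as tab-delimited text with header row and row labels.

    Values are written with full ``repr`` precision so that
    ``read_matrix(write_matrix(m))`` reproduces ``m`` exactly.
    """
    path = Path(path)
    m = np.atleast_2d(np.asarray(m, dtype=float))
    n_rows, n_cols = m.shape if m.size else (0, 0)
    if m.size == 0:
        n_rows, n_cols = m.shape
    if row_names is None:
        row_names = [f"r{i + 1}" for i in range(n_rows)]
    if col_names is None:
        col_names = [f"c{j + 1}" for j in range(n_cols)]
    if len(row_names) != n_rows or len(col_names) != n_cols:
        raise DimensionError(
            f"names ({len(row_names)}×{len(col_names)}) do not match "
            f"matrix shape {m.shape}"
        )
    df = pd.DataFrame(m, index=row_names, columns=col_names)
    df.to_csv(path, sep="\t", index_label="row", encoding="utf-8")
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix written by :func:`write_matrix`.

    Returns ``(values, row_names, col_names)``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    """Write a DataFrame as tab-delimited text without the index."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path
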