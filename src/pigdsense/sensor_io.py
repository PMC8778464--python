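"""Reading and writing thigh-IMU recordings and the subject table.

One CSV file per test, header ``t,ax,ay,az,gx,gy,gz``; acceleration in g,
angular velocity in deg/s.  The axis convention is the one used throughout
the package: when the wearer stands still, the y axis points opposite to
gravity (standing-rest median of ``ay`` is about +1 g) and x lies in the
frontal plane, so rotation about x is the thigh pitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImuRecording",
    "FormatError",
    "read_csv",
    "write_csv",
    "apply_frame_alignment",
    "read_subject_table",
    "write_subject_table",
]

CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]

SUBJECT_COLUMNS = ["subject_id", "condition", "pigd", "updrs3", "fog_status"]

#: Relative tolerance on sample spacing uniformity.
_UNIFORMITY_RTOL = 0.01


class FormatError(ValueError):
    """Raised when a recording file violates the expected layout."""


@dataclass
class ImuRecording:
    """Tri-axial accelerometer + gyroscope samples for one test.

    Attributes
    ----------
    subject_id : str
        Identifier of the wearer.
    condition : str
        Pharmacological state label, ``"ON"`` or ``"OFF"``.
    sample_rate : float
        Nominal sampling frequency in Hz.
    t : ndarray, shape (n,)
        Sample timestamps in seconds, strictly increasing and uniform.
    accel : ndarray, shape (n, 3)
        Acceleration (ax, ay, az) in g.
    gyro : ndarray, shape (n, 3)
        Angular velocity (gx, gy, gz) in deg/s.
    frame_note : str
        Free-text axis-convention reminder.
    """

    subject_id: str
    condition: str
    sample_rate: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    frame_note: str = "standing: +y anti-gravity, x frontal plane"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise FormatError(
                f"channel length mismatch: t has {n} samples, "
                f"accel {self.accel.shape}, gyro {self.gyro.shape}"
            )
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise FormatError(f"timestamps not strictly increasing at sample {bad}")
            nominal = 1.0 / self.sample_rate
            if np.any(np.abs(dt - nominal) > _UNIFORMITY_RTOL * nominal):
                bad = int(np.argmax(np.abs(dt - nominal) > _UNIFORMITY_RTOL * nominal)) + 1
                raise FormatError(
                    f"non-uniform sampling at sample {bad}: dt={dt[bad - 1]:.6f}s, "
                    f"expected {nominal:.6f}s within {100 * _UNIFORMITY_RTOL:.0f}%"
                )
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples else 0.0

    def equals(self, other: "ImuRecording", atol: float = 0.0) -> bool:
        return (
            self.subject_id == other.subject_id
            and self.condition == other.condition
            and math.isclose(self.sample_rate, other.sample_rate, rel_tol=1e-5)
            and np.allclose(self.t, other.t, atol=atol, rtol=0)
            and np.allclose(self.accel, other.accel, atol=atol, rtol=0)
            and np.allclose(self.gyro, other.gyro, atol=atol, rtol=0)
        )


def read_csv(
    path: str | Path,
    subject_id: str | None = None,
    condition: str | None = None,
    sample_rate: float | None = None,
) -> ImuRecording:
    """Load one per-test CSV file into a validated :class:`ImuRecording`.

    ``subject_id`` and ``condition`` default to values parsed from a
    ``<subject>_<condition>.csv`` file name; ``sample_rate`` is inferred
    from the median timestamp spacing when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (line 1)")
    for col in CSV_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            line = int(values.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-numeric value in column {col!r} (line {line})")
        df[col] = values
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    t = df["t"].to_numpy(dtype=float)
    if sample_rate is None:
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer sample rate from one sample")
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    if subject_id is None or condition is None:
        stem_parts = path.stem.rsplit("_", 1)
        if subject_id is None:
            subject_id = stem_parts[0]
        if condition is None:
            condition = stem_parts[1] if len(stem_parts) == 2 else "ON"
    try:
        return ImuRecording(
            subject_id=subject_id,
            condition=condition,
            sample_rate=float(sample_rate),
            t=t,
            accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
            gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_csv(rec: ImuRecording, path: str | Path) -> Path:
    """Write a recording in the per-test CSV dialect (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([rec.t, rec.accel, rec.gyro])
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for row in data:
            fh.write(",".join(format(v, ".12g") for v in row) + "\n")
    return path


def apply_frame_alignment(rec: ImuRecording, rotation: np.ndarray) -> ImuRecording:
    """Rotate both vector channels by a fixed sensor-to-body rotation matrix.

    The matrix must be orthonormal with determinant +1 (within 1e-6); the
    per-sample vector norms are preserved exactly up to floating error.
    """
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation matrix is not orthonormal within 1e-6")
    if np.linalg.det(rotation) < 0:
        raise ValueError("rotation matrix is a reflection (det < 0)")
    return replace(
        rec,
        accel=rec.accel @ rotation.T,
        gyro=rec.gyro @ rotation.T,
    )


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Load the subject metadata table (one row per subject per condition)."""
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: subject table missing columns {missing}")
    if (df["pigd"] < 0).any():
        raise FormatError(f"{path}: negative pigd score")
    dup = df.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (subject_id, condition) rows")
    return df[SUBJECT_COLUMNS + [c for c in df.columns if c not in SUBJECT_COLUMNS]]


def write_subject_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\n")
    return path
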