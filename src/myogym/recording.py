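"""Eight-channel surface-EMG recordings and their on-disk format.

A recording is the unit of the training protocol: one movement performed at a
graded fraction of maximum voluntary contraction (MVC) while the subject
tracks a trapezoidal force reference. On disk a recording is a delimited text
file (one column per electrode channel, one row per sample) plus a JSON
sidecar holding the metadata and the aligned reference trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Movement labels, in the fixed output order of the regressor.
MOVEMENTS: tuple[str, ...] = (
    "fine_pinch",
    "lateral_pinch",
    "wrist_rotation_cw",
    "wrist_rotation_ccw",
    "wrist_flexion",
    "wrist_extension",
    "hand_open",
)

#: Label for relaxed-muscle recordings (all-zero regression targets).
REST = "rest"

#: Arm postures used during the recording protocol.
POSTURES: tuple[str, ...] = ("hanging", "armrest", "reaching")

#: Graded contraction levels, as fractions of MVC.
LEVELS: tuple[float, ...] = (0.3, 0.6, 0.9)

N_CHANNELS = 8


@dataclass
class EmgRecording:
    """One multi-channel EMG trial with its protocol metadata.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, 8)
        Raw EMG, millivolt-scale arbitrary units, one column per electrode.
    fs : float
        Sampling rate in Hz.
    movement : str
        One of :data:`MOVEMENTS`, or ``"rest"``.
    level : float
        Target contraction level as a fraction of MVC (1.0 for MVC trials,
        0.0 for rest).
    posture : str
        One of :data:`POSTURES`.
    reference : ndarray, shape (n_samples,)
        Trapezoidal force reference aligned sample-for-sample to the signal,
        in fractions of MVC.
    recorded_at : str, optional
        Free-form provenance tag (kept deterministic by callers: it is a
        protocol index, never a wall-clock time).
    """

    signal: np.ndarray
    fs: float
    movement: str
    level: float
    posture: str
    reference: np.ndarray
    recorded_at: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != N_CHANNELS:
            raise ValueError(
                f"signal must have shape (n_samples, {N_CHANNELS}), "
                f"got {self.signal.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.reference.shape != (self.signal.shape[0],):
            raise ValueError("reference must be aligned to the signal")
        if self.movement != REST and self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement label {self.movement!r}")
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs


@dataclass
class Procedure:
    """One EMG recording procedure: all trials recorded in one sitting.

    In the protocol a procedure covers every currently trained movement: an
    MVC baseline followed by one trapezoid-tracked trial at each graded
    level, all performed in a single arm posture.
    """

    index: int
    posture: str
    recordings: list[EmgRecording] = field(default_factory=list)


def write_recording(rec: EmgRecording, csv_path: str | Path) -> Path:
    """Write a recording as CSV plus a JSON sidecar.

    The sidecar lives next to the CSV with the suffix replaced by ``.json``.
    Output bytes are deterministic for identical recordings.
    """
    csv_path = Path(csv_path)
    header = ",".join(f"channel_{i + 1}" for i in range(N_CHANNELS))
    np.savetxt(csv_path, rec.signal, delimiter=",", fmt="%.6f",
               header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "movement": rec.movement,
        "level": rec.level,
        "posture": rec.posture,
        "reference": [round(float(v), 6) for v in rec.reference],
        "recorded_at": rec.recorded_at,
    }
    csv_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=None, separators=(",", ":")) + "\n"
    )
    return csv_path


def read_recording(csv_path: str | Path) -> EmgRecording:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar_path} for {csv_path}"
        )
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in ("fs", "movement", "level", "posture", "reference"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing field {key!r}")
    signal = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    return EmgRecording(
        signal=signal,
        fs=float(meta["fs"]),
        movement=str(meta["movement"]),
        level=float(meta["level"]),
        posture=str(meta["posture"]),
        reference=np.asarray(meta["reference"], dtype=float),
        recorded_at=meta.get("recorded_at"),
    )
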