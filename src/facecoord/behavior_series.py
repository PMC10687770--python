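"""Assembly of the per-participant behavior matrix.

Expression-coefficient series (53 channels after dropping nose/cheeks) and
head-rotation angle series (yaw, pitch, roll in degrees) are stacked into a
single 56 x T channel-by-frame matrix, the central object of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "POSE_CHANNELS",
    "ExpressionSeries",
    "PoseSeries",
    "BehaviorMatrix",
    "rotation_to_euler",
    "euler_to_rotation",
    "assemble_behavior",
    "interpolate_gaps",
]

POSE_CHANNELS = ("pose_yaw", "pose_pitch", "pose_roll")

GIMBAL_TOL_DEG = 1e-6 * 180.0 / np.pi  # |pitch - 90 deg| below this flags lock


@dataclass(frozen=True)
class ExpressionSeries:
    """Per-frame expression coefficients, shape ``(T, n_channels)``."""

    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if vals.ndim != 2 or vals.shape[0] < 1:
            raise ValueError(f"values must be (T, C) with T >= 1, got {vals.shape}")
        if vals.shape[1] != len(self.channel_names):
            raise ValueError("one name per channel required")
        if not np.isfinite(vals).all():
            raise ValueError("expression series must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PoseSeries:
    """Per-frame head-rotation angles in degrees, columns yaw, pitch, roll."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", ang)
        if ang.ndim != 2 or ang.shape[1] != 3:
            raise ValueError(f"angles must be (T, 3), got {ang.shape}")
        if not ((ang > -180.0) & (ang <= 180.0)).all():
            raise ValueError("angles must lie in (-180, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]


@dataclass(frozen=True)
class BehaviorMatrix:
    """Channel-by-frame behavior matrix: expression rows then pose rows."""

    values: np.ndarray
    channel_descriptors: tuple[str, ...]
    frame_rate: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(
            self, "channel_descriptors", tuple(self.channel_descriptors)
        )
        if vals.ndim != 2:
            raise ValueError("values must be 2-D (channels x frames)")
        if vals.shape[0] != len(self.channel_descriptors):
            raise ValueError("one descriptor per channel row required")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_file(self, path) -> None:
        """Write as delimited text, one row per frame, header = descriptors."""
        pd.DataFrame(self.values.T, columns=list(self.channel_descriptors)).to_csv(
            path, index=False
        )

    @classmethod
    def from_file(cls, path, frame_rate: float) -> "BehaviorMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy().T, tuple(df.columns), frame_rate)


def rotation_to_euler(rotation: np.ndarray) -> tuple[float, float, float, bool]:
    """Decompose a rotation matrix into intrinsic yaw-pitch-roll (degrees).

    Convention: intrinsic Z-Y-X — yaw about the vertical axis first, then
    pitch, then roll.  Recomposing the returned angles reproduces the input
    to 1e-6 away from gimbal lock.

    Returns ``(yaw, pitch, roll, gimbal_locked)``.  At gimbal lock
    (|pitch| within 1e-6 rad of 90 deg) yaw and roll are not separable;
    roll is set to 0, the combined angle is assigned to yaw and the flag is
    raised.
    """
    rot = np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6) or not np.isclose(
        np.linalg.det(rot), 1.0, atol=1e-6
    ):
        raise ValueError("matrix is not a proper rotation (orthogonal, det +1)")
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; we detect and flag it explicitly below
        warnings.simplefilter("ignore", UserWarning)
        yaw, pitch, roll = Rotation.from_matrix(rot).as_euler("ZYX", degrees=True)
    locked = abs(abs(pitch) - 90.0) < GIMBAL_TOL_DEG
    if locked:
        # scipy already folds the degenerate direction into the first angle
        roll = 0.0
    return float(yaw), float(pitch), float(roll), locked


def euler_to_rotation(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """Inverse of :func:`rotation_to_euler` (intrinsic Z-Y-X, degrees)."""
    return Rotation.from_euler("ZYX", [yaw, pitch, roll], degrees=True).as_matrix()


def pose_from_rotations(rotations: np.ndarray) -> PoseSeries:
    """Convert a ``(T, 3, 3)`` stack of rotation matrices to a pose series."""
    angles = np.array(
        [rotation_to_euler(r)[:3] for r in np.asarray(rotations, dtype=float)]
    )
    angles[angles == -180.0] = 180.0  # fold the branch cut into (-180, 180]
    return PoseSeries(angles)


def assemble_behavior(
    expr: ExpressionSeries, pose: PoseSeries, frame_rate: float
) -> BehaviorMatrix:
    """Stack expression channels over pose channels into one matrix.

    Rows 0..C-1 are the expression channels (series transposed to
    channel-major); the last three rows are yaw, pitch, roll.
    """
    if expr.n_frames != pose.n_frames:
        raise ValueError(
            f"length mismatch: expression has {expr.n_frames} frames, "
            f"pose has {pose.n_frames}"
        )
    values = np.vstack([expr.values.T, pose.angles.T])
    descriptors = expr.channel_names + POSE_CHANNELS
    return BehaviorMatrix(values, descriptors, frame_rate)


def interpolate_gaps(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate over flagged-invalid frames, per channel.

    Off by default in the pipeline (inputs are expected gap-free); provided
    as a pre-step utility.  ``values`` is ``(T, C)``; ``valid`` a boolean
    ``(T,)`` mask.  Edge gaps are filled by nearest valid value.
    """
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("no valid frames to interpolate from")
    out = values.copy()
    t = np.arange(values.shape[0])
    for c in range(values.shape[1]):
        out[~valid, c] = np.interp(t[~valid], t[valid], values[valid, c])
    return out
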