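"""Motion-label derivation from elbow-joint kinematics.

This is a documented stand-in rule for users importing real kinematic data:
the class of each 20 Hz frame is decided by thresholding the elbow angular
velocity, with a hysteresis band to prevent label chatter near the
threshold.  Synthetic data bypasses this module entirely (its labels are
ground truth by construction), and the exact rule used with the original
recordings (which also involved angular acceleration) is not public -- treat
thresholds as instrument- and task-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import MotionLabels

__all__ = ["JointKinematics", "derive_labels"]


@dataclass
class JointKinematics:
    """Elbow angle trace at the 20 Hz frame rate, with derivatives.

    Angular velocity (deg/s) and acceleration (deg/s^2) are computed by
    central differences (one-sided at the ends).
    """

    elbow_angle: np.ndarray
    fs: float = 20.0

    def __post_init__(self):
        self.elbow_angle = np.asarray(self.elbow_angle, dtype=float)
        if self.elbow_angle.ndim != 1 or self.elbow_angle.size < 3:
            raise ValueError("elbow_angle must be a 1-D trace of >= 3 samples")
        if not np.isfinite(self.elbow_angle).all():
            raise ValueError("elbow_angle contains non-finite values")

    @property
    def angular_velocity(self) -> np.ndarray:
        return np.gradient(self.elbow_angle) * self.fs

    @property
    def angular_acceleration(self) -> np.ndarray:
        return np.gradient(self.angular_velocity) * self.fs


def derive_labels(
    kin: JointKinematics, vel_threshold: float, hysteresis: float = 0.0
) -> MotionLabels:
    """Threshold the angular velocity into rest / flexion / extension.

    ``flexion`` when velocity exceeds ``+vel_threshold``, ``extension`` below
    ``-vel_threshold``, ``rest`` otherwise.  Once a motion label is active it
    is retained until |velocity| falls below ``vel_threshold - hysteresis``
    (the hysteresis band suppresses chatter at the threshold).  Negating the
    angle trace swaps flexion and extension exactly.
    """
    if not vel_threshold > hysteresis >= 0:
        raise ValueError("require vel_threshold > hysteresis >= 0")
    v = kin.angular_velocity
    release = vel_threshold - hysteresis
    labels = np.empty(v.size, dtype=np.int64)
    state = 0
    for i, vi in enumerate(v):
        if vi > vel_threshold:
            state = 1
        elif vi < -vel_threshold:
            state = 2
        elif state == 1 and vi < release:
            state = 0
        elif state == 2 and vi > -release:
            state = 0
        labels[i] = state
    return MotionLabels(labels, fs_labels=kin.fs)
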