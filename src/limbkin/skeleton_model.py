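"""Depth-camera (skeleton) kinematic model.

Builds torso and right upper-arm frames from tracked skeleton joints,
decomposes the shoulder rotation with the same intrinsic flexion →
adduction → internal-rotation sequence as the marker model (one shared
implementation in :mod:`limbkin.euler`), and computes elbow flexion directly
from the shoulder-elbow-wrist joint triangle.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError
from .euler import decompose_shoulder, relative_rotation
from .frames import assemble, build_upper_arm_frame, unit
from .marker_model import elbow_flexion_from_centres
from .types import JointAngleSeries, SegmentFrameSeries, SkeletonTrial

_MIN_SIN = 1e-6


def build_torso_frame_skeleton(trial: SkeletonTrial) -> SegmentFrameSeries:
    """Torso frame: origin SpineShoulder, Y along SpineMid→SpineShoulder.

    X is perpendicular to Y and to the shoulder line, pointing anteriorly
    (X = Y × (ShoulderRight − ShoulderLeft) in subject-fixed coordinates);
    Z = X × Y completes the right-handed frame and points laterally.
    """
    ss, sm = trial["SpineShoulder"], trial["SpineMid"]
    sr, sl = trial["ShoulderRight"], trial["ShoulderLeft"]
    Y = unit(ss - sm)
    shoulder_line = sr - sl
    X0 = np.cross(Y, shoulder_line)
    nn = np.linalg.norm(X0, axis=-1)
    if np.any(nn < _MIN_SIN * np.linalg.norm(shoulder_line, axis=-1)):
        raise DegenerateGeometryError("shoulder line parallel to the spine axis")
    X = X0 / nn[:, None]
    Z = np.cross(X, Y)
    return assemble(ss, X, Y, Z, "torso")


def build_upper_arm_frame_skeleton(trial: SkeletonTrial) -> SegmentFrameSeries:
    """Right upper-arm frame from ShoulderRight/ElbowRight/WristRight."""
    torso = build_torso_frame_skeleton(trial)
    lateral_ref = torso.rotation[:, :, 2]
    return build_upper_arm_frame(
        trial["ShoulderRight"], trial["ElbowRight"], trial["WristRight"], lateral_ref
    )


def elbow_flexion_skeleton(trial: SkeletonTrial) -> tuple[np.ndarray, np.ndarray]:
    """Elbow flexion (degrees, 0 = straight arm) and validity mask."""
    return elbow_flexion_from_centres(
        trial["ShoulderRight"], trial["ElbowRight"], trial["WristRight"]
    )


def joint_angles_skeleton(trial: SkeletonTrial) -> JointAngleSeries:
    """Four joint-angle channels from a skeleton trial."""
    torso = build_torso_frame_skeleton(trial)
    upper = build_upper_arm_frame_skeleton(trial)
    fe, aa, ie, gimbal = decompose_shoulder(relative_rotation(torso.rotation, upper.rotation))
    el_fe, el_ok = elbow_flexion_skeleton(trial)

    angles = np.column_stack([fe, aa, ie, el_fe])
    valid = np.ones_like(angles, dtype=bool)
    valid[:, :3] &= (~gimbal)[:, None] & upper.valid[:, None]
    valid[:, 3] &= el_ok
    return JointAngleSeries(time=trial.time, angles=angles, valid=valid)
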