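"""Shoulder Euler decomposition shared by both kinematic models.

The humerus-relative-to-torso rotation is decomposed as an *intrinsic*
Z-X-Y sequence on the anatomical frames (columns X anterior, Y longitudinal/
up, Z right-lateral):

1. flexion(+)/extension(−) about the torso mediolateral axis (Z),
2. adduction(+)/abduction(−) about the floating anteroposterior axis (X),
3. internal(+)/external(−) rotation about the humeral longitudinal axis (Y).

With these axes the right-hand rule reproduces the clinical sign convention
for the right arm directly, so no per-channel sign flips are needed.  The
sequence is singular when the second angle approaches ±90°; affected samples
are flagged (angles are still reported) so statistics can mask them.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DomainError

#: scipy intrinsic-sequence string matching the decomposition above.
_SEQ = "ZXY"

#: |adduction/abduction| this close to 90° (degrees) flags gimbal proximity.
GIMBAL_MARGIN_DEG = 1.0


def recompose_shoulder(fe, aa, ie) -> np.ndarray:
    """Rotation matrices from flexion, adduction, internal-rotation angles.

    Parameters are in degrees, scalars or equal-length arrays; returns
    (3, 3) or (T, 3, 3).
    """
    fe, aa, ie = np.broadcast_arrays(np.asarray(fe, float), np.asarray(aa, float), np.asarray(ie, float))
    ang = np.stack([fe, aa, ie], axis=-1)
    squeeze = ang.ndim == 1
    R = Rotation.from_euler(_SEQ, np.atleast_2d(ang), degrees=True).as_matrix()
    return R[0] if squeeze else R


def decompose_shoulder(R) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Decompose relative rotation(s) into (fe, aa, ie) degrees + gimbal flag.

    ``R`` is (3, 3) or (T, 3, 3); returns four arrays (fe, aa, ie, gimbal)
    with gimbal True where |aa| is within :data:`GIMBAL_MARGIN_DEG` of 90°.
    Angles lie in (−180, 180]; aa in [−90, 90] by construction of the
    sequence.
    """
    R = np.asarray(R, dtype=float)
    squeeze = R.ndim == 2
    R3 = R[None] if squeeze else R
    if R3.ndim != 3 or R3.shape[-2:] != (3, 3):
        raise DomainError("R must be a (3, 3) or (T, 3, 3) rotation array")
    ang = Rotation.from_matrix(R3).as_euler(_SEQ, degrees=True)
    fe, aa, ie = ang[:, 0], ang[:, 1], ang[:, 2]
    gimbal = np.abs(np.abs(aa) - 90.0) < GIMBAL_MARGIN_DEG
    if squeeze:
        return fe[0], aa[0], ie[0], gimbal[0]
    return fe, aa, ie, gimbal


def relative_rotation(torso_R: np.ndarray, upper_arm_R: np.ndarray) -> np.ndarray:
    """Humerus orientation expressed in the torso frame: R_tᵀ · R_ua."""
    torso_R = np.asarray(torso_R, float)
    upper_arm_R = np.asarray(upper_arm_R, float)
    return np.swapaxes(torso_R, -1, -2) @ upper_arm_R
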