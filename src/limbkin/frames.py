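"""Shared segment-frame construction utilities.

Both kinematic models build the right upper-arm frame the same way (origin at
the elbow centre, Y toward the shoulder, Z perpendicular to the humerus-
forearm plane pointing laterally, X = Y × Z anteriorly), so the construction
lives here once.

Lateral/anterior disambiguation is resolved *per trial*, not per frame: the
candidate Z axis is flipped once if its median projection on a lateral
reference direction is negative.  With the arm fully extended the humerus-
forearm plane is undefined; frames where the sine of the humerus/forearm
angle falls below ``EXTENSION_SIN_MIN`` reuse the nearest well-conditioned Z
direction and are flagged invalid.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError
from .types import SegmentFrameSeries

#: sin of the humerus/forearm angle below which the arm counts as straight.
EXTENSION_SIN_MIN = 0.05


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; raises on (near-)zero norm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise DegenerateGeometryError("cannot normalize a zero-length vector")
    return v / n


def orient_trialwise(axis: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip ``axis`` (T, 3) once per trial so it points along ``reference``.

    The sign is decided from the median per-frame projection, so individual
    noisy frames cannot flip the convention mid-trial.
    """
    proj = np.einsum("ij,ij->i", axis, np.broadcast_to(reference, axis.shape))
    return -axis if np.median(proj) < 0 else axis


def assemble(origin: np.ndarray, X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
             segment: str, valid: np.ndarray | None = None) -> SegmentFrameSeries:
    """Stack per-frame axes (columns X, Y, Z) into a SegmentFrameSeries."""
    R = np.stack([X, Y, Z], axis=-1)
    return SegmentFrameSeries(segment=segment, origin=origin, rotation=R, valid=valid)


def build_upper_arm_frame(
    shoulder: np.ndarray,
    elbow: np.ndarray,
    wrist: np.ndarray,
    lateral_ref: np.ndarray,
) -> SegmentFrameSeries:
    """Right upper-arm anatomical frame from joint-centre trajectories.

    Parameters are (T, 3) world trajectories of the shoulder, elbow and
    wrist centres; ``lateral_ref`` is a (3,) or (T, 3) direction with a
    positive component toward the subject's right, used to orient Z.
    """
    shoulder, elbow, wrist = (np.asarray(a, float) for a in (shoulder, elbow, wrist))
    Y = unit(shoulder - elbow)
    forearm = wrist - elbow
    fa_norm = np.linalg.norm(forearm, axis=-1)
    if np.any(fa_norm < 1e-12):
        raise DegenerateGeometryError("wrist and elbow centres coincide")
    Z0 = np.cross(Y, forearm)
    sin_angle = np.linalg.norm(Z0, axis=-1) / fa_norm
    ok = sin_angle >= EXTENSION_SIN_MIN

    T = Y.shape[0]
    Z = np.empty_like(Y)
    if not np.any(ok):
        raise DegenerateGeometryError(
            "arm fully extended for the entire trial: upper-arm Z axis undefined"
        )
    Z[ok] = Z0[ok] / np.linalg.norm(Z0[ok], axis=-1, keepdims=True)
    # fill degenerate frames with the nearest well-conditioned direction
    if not np.all(ok):
        idx_ok = np.flatnonzero(ok)
        nearest = idx_ok[np.searchsorted(idx_ok, np.flatnonzero(~ok)).clip(0, len(idx_ok) - 1)]
        # prefer the previous good frame where one exists
        for bad, near in zip(np.flatnonzero(~ok), nearest):
            prev = idx_ok[idx_ok < bad]
            Z[bad] = Z[prev[-1]] if len(prev) else Z[near]

    lateral_ref = np.broadcast_to(np.asarray(lateral_ref, float), (T, 3))
    Z = orient_trialwise(Z, lateral_ref)
    # re-orthogonalize carried-forward Z against the current Y
    Z = unit(Z - np.einsum("ij,ij->i", Z, Y)[:, None] * Y)
    X = np.cross(Y, Z)
    return assemble(elbow, X, Y, Z, "upper_arm", valid=ok)
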