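"""Reference (marker-based) kinematic model.

Builds torso and right upper-arm anatomical frames from the marker set
(spinal/sternal landmarks, shoulder markers, elbow epicondyles, wrist
styloids and two rigid 3-marker clusters), reconstructs the removable
elbow/wrist landmarks with the calibrated-cluster technique, and computes
the four joint-angle channels that serve as the gold standard downstream.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError, MissingMarkerError
from .euler import decompose_shoulder, relative_rotation
from .frames import assemble, build_upper_arm_frame, orient_trialwise, unit
from .types import CastCalibration, JointAngleSeries, MarkerTrial, SegmentFrameSeries

#: Landmarks reconstructed from clusters, and the cluster that carries each.
CAST_LANDMARKS = {"EL": "PUA", "EM": "PUA", "RS": "DUA", "US": "DUA"}

_MIN_SIN = 1e-6  # collinearity guard for plane normals


def build_torso_frame_marker(trial: MarkerTrial) -> SegmentFrameSeries:
    """Torso anatomical frame: origin C7, Y along T10→C7, Z lateral.

    Z is the unit normal of the sagittal plane through T10, C7 and CLAV,
    oriented toward the subject's right using the shoulder markers; X = Y × Z.
    """
    c7, t10, clav = trial["C7"], trial["T10"], trial["CLAV"]
    spine = c7 - t10
    Y = unit(spine)
    normal = np.cross(spine, clav - t10)
    nn = np.linalg.norm(normal, axis=-1)
    if np.any(nn < _MIN_SIN * np.linalg.norm(spine, axis=-1) * np.linalg.norm(clav - t10, axis=-1)):
        raise DegenerateGeometryError("T10, C7 and CLAV are collinear: sagittal plane undefined")
    Z = normal / nn[:, None]
    lateral_ref = 0.5 * (trial["ASH"] + trial["PSH"]) - c7  # toward the right shoulder
    Z = orient_trialwise(Z, lateral_ref.mean(axis=0))
    X = np.cross(Y, Z)
    return assemble(c7, X, Y, Z, "torso")


def _cluster_frame(m1: np.ndarray, m2: np.ndarray, m3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Technical frame of a 3-marker cluster: origin m1, X toward m2."""
    X = unit(m2 - m1)
    v3 = m3 - m1
    Z0 = np.cross(X, v3)
    nn = np.linalg.norm(Z0, axis=-1)
    if np.any(nn < _MIN_SIN * np.linalg.norm(v3, axis=-1)):
        raise DegenerateGeometryError("cluster markers are collinear")
    Z = Z0 / nn[:, None]
    Y = np.cross(Z, X)
    R = np.stack([X, Y, Z], axis=-1)
    return m1, R


def _cluster_pose(trial: MarkerTrial, cluster: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        m1, m2, m3 = (trial[f"{cluster}{i}"] for i in (1, 2, 3))
    except MissingMarkerError as exc:
        raise MissingMarkerError(f"cluster {cluster} incomplete") from exc
    return _cluster_frame(m1, m2, m3)


def cast_calibrate(static: MarkerTrial) -> CastCalibration:
    """Express the removable elbow/wrist landmarks in their cluster frames.

    Averages the landmark's local coordinates over all frames of the static
    trial; the returned calibration reports the mean reconstruction residual
    on that same trial (sub-millimetre for a rigid, low-noise capture).
    """
    if not static.is_static:
        raise MissingMarkerError("cast_calibrate requires the static calibration trial")
    local, residuals = {}, []
    for landmark, cluster in CAST_LANDMARKS.items():
        origin, R = _cluster_pose(static, cluster)
        p = static[landmark]
        loc = np.einsum("tij,tj->ti", np.swapaxes(R, -1, -2), p - origin)
        local[landmark] = loc.mean(axis=0)
        rec = origin + np.einsum("tij,j->ti", R, local[landmark])
        residuals.append(np.linalg.norm(rec - p, axis=-1).mean())
    return CastCalibration(local_coords=local, cluster_of=dict(CAST_LANDMARKS),
                           residual=float(np.mean(residuals)))


def cast_reconstruct(dynamic: MarkerTrial, calib: CastCalibration) -> MarkerTrial:
    """Return ``dynamic`` augmented with reconstructed EL, EM, RS, US."""
    trajs = dict(dynamic.trajectories)
    for landmark, cluster in calib.cluster_of.items():
        origin, R = _cluster_pose(dynamic, cluster)
        trajs[landmark] = origin + np.einsum("tij,j->ti", R, calib.local_coords[landmark])
    out = MarkerTrial(fs=dynamic.fs, trajectories=trajs, subject=dynamic.subject,
                      session=dynamic.session, task=dynamic.task, trial=dynamic.trial,
                      is_static=dynamic.is_static, device=dynamic.device)
    return out


def _joint_centres(trial: MarkerTrial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shoulder = 0.5 * (trial["ASH"] + trial["PSH"])
    elbow = 0.5 * (trial["EL"] + trial["EM"])
    wrist = 0.5 * (trial["RS"] + trial["US"])
    return shoulder, elbow, wrist


def build_upper_arm_frame_marker(trial: MarkerTrial) -> SegmentFrameSeries:
    """Right upper-arm frame from (possibly reconstructed) landmark markers."""
    shoulder, elbow, wrist = _joint_centres(trial)
    torso = build_torso_frame_marker(trial)
    lateral_ref = torso.rotation[:, :, 2]  # torso Z axis, points right
    return build_upper_arm_frame(shoulder, elbow, wrist, lateral_ref)


def elbow_flexion_from_centres(shoulder: np.ndarray, elbow: np.ndarray,
                               wrist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elbow flexion in degrees (0 = full extension) plus validity mask."""
    u = shoulder - elbow
    v = wrist - elbow
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    ok = (nu > 1e-9) & (nv > 1e-9)
    cosang = np.zeros(u.shape[0])
    cosang[ok] = np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])
    theta = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta[~ok] = np.nan
    return theta, ok


def joint_angles_marker(trial: MarkerTrial, calib: CastCalibration | None = None) -> JointAngleSeries:
    """Four joint-angle channels from a marker trial.

    If the elbow/wrist landmarks were removed for the dynamic capture, pass
    the static-trial calibration so they are reconstructed from the clusters.
    Degenerate (straight-arm) and gimbal-proximal samples are masked.
    """
    if calib is not None and any(l not in trial.trajectories for l in CAST_LANDMARKS):
        trial = cast_reconstruct(trial, calib)
    torso = build_torso_frame_marker(trial)
    upper = build_upper_arm_frame_marker(trial)
    fe, aa, ie, gimbal = decompose_shoulder(relative_rotation(torso.rotation, upper.rotation))

    shoulder, elbow, wrist = _joint_centres(trial)
    el_fe, el_ok = elbow_flexion_from_centres(shoulder, elbow, wrist)

    angles = np.column_stack([fe, aa, ie, el_fe])
    valid = np.ones_like(angles, dtype=bool)
    valid[:, :3] &= (~gimbal)[:, None] & upper.valid[:, None]
    valid[:, 3] &= el_ok
    return JointAngleSeries(time=trial.time, angles=angles, valid=valid)
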