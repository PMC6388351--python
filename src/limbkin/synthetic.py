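"""Synthetic dual-device motion generator.

Produces ground-truth joint-angle trajectories for the four functional reach
tasks and renders them through a forward-kinematic chain into the two
recordings every downstream stage consumes:

* a marker-trajectory trial at 100 Hz (reference device), including the
  static calibration trial required by the cluster-calibration step, and
* a skeleton-joint trial at 30 Hz (depth camera) with an optional unknown
  time offset, per-channel angle bias and smooth angle noise emulating
  pose-estimation error, and additive joint-position noise.

World frame: origin at the C7 landmark, X anterior, Y up, Z to the subject's
right.  The torso is stationary; only the right arm moves.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError, DomainError
from .euler import recompose_shoulder
from .types import (
    Anthropometry,
    GroundTruthMotion,
    JointAngleSeries,
    MarkerTrial,
    NoiseModel,
    SkeletonTrial,
    Task,
    TaskDefinition,
)

MARKER_FS = 100.0    #: nominal marker-device sampling rate, Hz
SKELETON_FS = 30.0   #: nominal depth-camera sampling rate, Hz


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ on τ ∈ [0, 1]."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return tau ** 3 * (10.0 + tau * (-15.0 + 6.0 * tau))


def _variability(tau: np.ndarray, sd: float, rng: np.random.Generator, n_harmonics: int = 4) -> np.ndarray:
    """Smooth, endpoint-vanishing within-trial variability (degrees)."""
    if sd <= 0:
        return np.zeros_like(tau)
    out = np.zeros_like(tau)
    for j in range(1, n_harmonics + 1):
        out += rng.normal(0.0, sd / j) * np.sin(np.pi * j * tau)
    return out


def generate_task_motion(
    task: TaskDefinition,
    fs: float = MARKER_FS,
    seed: int = 0,
    variability_sd: float = 0.0,
) -> GroundTruthMotion:
    """Ground-truth angle trajectories for one trial of ``task``.

    Each channel follows a minimum-jerk profile from its start to its end
    value; ``variability_sd`` (degrees) adds seeded, smooth, endpoint-
    vanishing within-trial variability.  The time grid spans [0, duration]
    with both endpoints included, so the first/last samples equal the
    start/end postures exactly.
    """
    if not isinstance(task, TaskDefinition):
        raise ConfigurationError("task must be a TaskDefinition")
    if not (fs > 0):
        raise DomainError(f"fs must be > 0, got {fs!r}")
    n = int(round(task.duration * fs)) + 1
    if n < 10:
        raise DomainError("duration x fs must give at least 10 samples")
    time = np.linspace(0.0, task.duration, n)
    tau = time / task.duration
    s = minimum_jerk(tau)
    angles = task.start_angles[None, :] + s[:, None] * (task.end_angles - task.start_angles)[None, :]
    if variability_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), 11]))
        for c in range(4):
            angles[:, c] += _variability(tau, variability_sd, rng)
    series = JointAngleSeries(time=time, angles=angles)
    return GroundTruthMotion(time=time, angles=series, task=task)


def angles_at(motion: GroundTruthMotion, t: np.ndarray) -> np.ndarray:
    """Ground-truth angles (T, 4) at arbitrary times, clamped to the trial span."""
    t = np.clip(np.asarray(t, dtype=float), motion.time[0], motion.time[-1])
    spl = CubicSpline(motion.time, motion.angles.angles, axis=0)
    return spl(t)


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

# Local marker offsets, metres.  Epicondyle/styloid markers straddle the
# elbow/wrist centres along the segment Z axis; cluster markers sit on rigid
# plates on the lateral segment surface (three non-collinear points each).
_EPICONDYLE_HALF = 0.035
_STYLOID_HALF = 0.025

_PUA_LOCAL = {  # upper-arm (humeral) frame, origin at shoulder centre
    "PUA1": np.array([0.020, -0.120, 0.045]),
    "PUA2": np.array([0.050, -0.150, 0.035]),
    "PUA3": np.array([0.020, -0.190, 0.050]),
}
_DUA_LOCAL = {  # forearm frame, origin at elbow centre
    "DUA1": np.array([0.020, -0.100, 0.030]),
    "DUA2": np.array([0.045, -0.130, 0.020]),
    "DUA3": np.array([0.020, -0.170, 0.035]),
}


def _rot_z(theta_deg: np.ndarray) -> np.ndarray:
    """(T, 3, 3) rotations about the segment Z (mediolateral) axis."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    c, s = np.cos(th), np.sin(th)
    R = np.zeros(th.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


class BodyPose:
    """Joint/marker world positions of the torso-arm chain for given angles."""

    def __init__(self, anthro: Anthropometry, angles: np.ndarray):
        if not isinstance(anthro, Anthropometry):
            raise ConfigurationError("anthro must be an Anthropometry instance")
        angles = np.atleast_2d(np.asarray(angles, dtype=float))
        if angles.shape[1] != 4:
            raise DomainError("angles must have shape (T, 4)")
        self.anthro = anthro
        sw, th = anthro.shoulder_width, anthro.torso_height
        self.shoulder = np.array([0.0, -0.03, sw / 2.0])
        # humeral and forearm segment rotations
        self.R_h = recompose_shoulder(angles[:, 0], angles[:, 1], angles[:, 2])
        self.R_f = self.R_h @ _rot_z(angles[:, 3])
        self.elbow = self.shoulder + self.R_h @ np.array([0.0, -anthro.upper_arm_length, 0.0])
        self.wrist = self.elbow + self.R_f @ np.array([0.0, -anthro.forearm_length, 0.0])
        self.n = angles.shape[0]
        # torso landmarks (stationary)
        self._torso = {
            "C7": np.array([0.0, 0.0, 0.0]),
            "T10": np.array([0.0, -th, 0.0]),
            "CLAV": np.array([0.06, -0.02, 0.0]),
            "STRN": np.array([0.09, -0.17, 0.0]),
            "ASH": self.shoulder + np.array([0.04, 0.0, 0.0]),
            "PSH": self.shoulder + np.array([-0.04, 0.0, 0.0]),
        }

    def markers(self) -> dict[str, np.ndarray]:
        """All marker trajectories (name -> (T, 3)) of the reference set."""
        T = self.n
        out = {k: np.broadcast_to(v, (T, 3)).copy() for k, v in self._torso.items()}
        ez = np.array([0.0, 0.0, 1.0])
        out["EL"] = self.elbow + self.R_h @ (ez * _EPICONDYLE_HALF)
        out["EM"] = self.elbow + self.R_h @ (-ez * _EPICONDYLE_HALF)
        out["RS"] = self.wrist + self.R_f @ (ez * _STYLOID_HALF)
        out["US"] = self.wrist + self.R_f @ (-ez * _STYLOID_HALF)
        for name, local in _PUA_LOCAL.items():
            out[name] = self.shoulder + self.R_h @ local
        for name, local in _DUA_LOCAL.items():
            out[name] = self.elbow + self.R_f @ local
        return out

    def skeleton_joints(self) -> dict[str, np.ndarray]:
        """Depth-camera skeleton joint trajectories (name -> (T, 3))."""
        T = self.n
        sw = self.anthro.shoulder_width
        fixed = {
            "SpineShoulder": np.array([0.0, -0.02, 0.0]),
            "SpineMid": np.array([0.0, -0.30, 0.0]),
            "ShoulderLeft": np.array([0.0, -0.03, -sw / 2.0]),
        }
        out = {k: np.broadcast_to(v, (T, 3)).copy() for k, v in fixed.items()}
        out["ShoulderRight"] = np.broadcast_to(self.shoulder, (T, 3)) + np.zeros((T, 3))
        out["ElbowRight"] = self.elbow
        out["WristRight"] = self.wrist
        out["HandRight"] = self.wrist + self.R_f @ np.array([0.0, -0.08, 0.0])
        return out


def _smooth_angle_noise(n: int, fs: float, sd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, 4) smooth per-channel angle perturbation with per-sample SD ``sd``.

    White noise low-passed (moving-window Gaussian smoothing, ~1.5 Hz) and
    rescaled so the realized per-channel standard deviation equals ``sd``.
    """
    out = np.zeros((n, 3 + 1))
    if np.all(sd <= 0):
        return out
    raw = rng.standard_normal((n, 4))
    # Gaussian smoothing kernel, sigma ~ fs/10 samples
    sigma = max(fs / 10.0, 1.0)
    half = int(4 * sigma)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= k.sum()
    for c in range(4):
        if sd[c] <= 0:
            continue
        padded = np.pad(raw[:, c], half, mode="reflect")
        smooth = np.convolve(padded, k, mode="valid")
        smooth -= smooth.mean()
        s = smooth.std()
        if s > 0:
            out[:, c] = smooth * (sd[c] / s)
    return out


def render_markers(
    motion: GroundTruthMotion,
    anthro: Anthropometry,
    noise: NoiseModel,
    fs: float = MARKER_FS,
    static_duration: float = 1.0,
    strip_landmarks: bool = False,
    lead_in: float = 0.0,
    lead_out: float = 0.0,
    **ids,
) -> tuple[MarkerTrial, MarkerTrial]:
    """Render a marker-device recording of ``motion``.

    Returns ``(dynamic, static)``: the dynamic trial sampled at ``fs`` and a
    static anatomical-position trial of ``static_duration`` seconds for
    cluster calibration.  Isotropic Gaussian noise of ``noise.marker_noise_sd``
    metres per axis is added to every marker of both trials.  With
    ``strip_landmarks=True`` the removable elbow/wrist landmarks (EL, EM,
    RS, US) are omitted from the dynamic trial, mimicking the capture
    protocol in which they exist only on the static trial and must be
    cluster-reconstructed dynamically.

    ``lead_in``/``lead_out`` seconds of quiet standing (posture held at the
    start/end angles) are recorded before and after the movement, as in a
    real capture; they also give the cross-correlation synchronizer its
    plateau-ramp-plateau shape.
    """
    if not (fs > 0):
        raise DomainError("fs must be > 0")
    if lead_in < 0 or lead_out < 0:
        raise DomainError("lead_in/lead_out must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[int(noise.seed), 0]))

    n_dyn = int(round((motion.time[-1] + lead_in + lead_out) * fs)) + 1
    t_dyn = np.arange(n_dyn) / fs - lead_in
    ang = angles_at(motion, t_dyn)
    dyn_markers = BodyPose(anthro, ang).markers()

    n_stat = max(int(round(static_duration * fs)), 2)
    stat_markers = BodyPose(anthro, np.zeros((n_stat, 4))).markers()

    if noise.marker_noise_sd > 0:
        for m in dyn_markers:
            dyn_markers[m] = dyn_markers[m] + rng.normal(0.0, noise.marker_noise_sd, (n_dyn, 3))
        for m in stat_markers:
            stat_markers[m] = stat_markers[m] + rng.normal(0.0, noise.marker_noise_sd, (n_stat, 3))

    if strip_landmarks:
        for lm in ("EL", "EM", "RS", "US"):
            dyn_markers.pop(lm, None)
    dynamic = MarkerTrial(fs=fs, trajectories=dyn_markers, is_static=False, device="marker", **ids)
    static = MarkerTrial(fs=fs, trajectories=stat_markers, is_static=True, device="marker", **ids)
    return dynamic, static


def render_skeleton(
    motion: GroundTruthMotion,
    anthro: Anthropometry,
    noise: NoiseModel,
    fs: float = SKELETON_FS,
    lead_in: float = 0.0,
    lead_out: float = 0.0,
    **ids,
) -> SkeletonTrial:
    """Render a depth-camera skeleton recording of ``motion``.

    The device clock starts ``noise.skeleton_time_offset`` seconds before the
    movement, so the recorded waveform is delayed by that offset relative to
    the marker device.  ``noise.angle_bias``, ``noise.angle_rom_bias`` and
    ``noise.angle_noise_sd`` (smooth, seeded) perturb the underlying joint
    angles before rendering — emulating systematic and stochastic
    skeleton-tracking error — and isotropic Gaussian position noise of
    ``noise.joint_noise_sd`` metres per axis is added to every joint.

    The systematic part is a two-parameter model of joint-angle tracking
    error.  At the goal posture the device reads ``angle_bias`` degrees off;
    its excursion is off by ``angle_rom_bias`` degrees, so at rest it reads
    ``angle_bias − sign(excursion) · angle_rom_bias`` off, and the offset
    relaxes between the two along the movement's minimum-jerk progress.
    With ``angle_rom_bias = 0`` this is a constant offset of ``angle_bias``.
    """
    if not (fs > 0):
        raise DomainError("fs must be > 0")
    if lead_in < 0 or lead_out < 0:
        raise DomainError("lead_in/lead_out must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[int(noise.seed), 1]))

    duration = motion.time[-1]
    span = duration + lead_in + lead_out + max(noise.skeleton_time_offset, 0.0)
    n = int(round(span * fs)) + 1
    t_device = np.arange(n) / fs - lead_in
    t_motion = t_device - noise.skeleton_time_offset
    ang = angles_at(motion, t_motion)
    progress = minimum_jerk(t_motion / duration)
    excursion = motion.angles.angles[-1] - motion.angles.angles[0]
    sgn = np.where(np.sign(excursion) == 0, 1.0, np.sign(excursion))
    rest_offset = np.asarray(noise.angle_bias) - sgn * np.asarray(noise.angle_rom_bias)
    ang = ang + rest_offset[None, :] + progress[:, None] * (noise.angle_bias - rest_offset)[None, :]
    ang = ang + _smooth_angle_noise(n, fs, noise.angle_noise_sd, rng)
    # the device reports anatomically representable angles; clamping keeps
    # the perturbed posture away from the |Add/Abd| = 90 deg singular branch
    lo = np.array([-178.0, -88.0, -118.0, 2.0])
    hi = np.array([178.0, 88.0, 118.0, 149.0])
    ang = np.clip(ang, lo, hi)

    joints = BodyPose(anthro, ang).skeleton_joints()
    if noise.joint_noise_sd > 0:
        for j in joints:
            joints[j] = joints[j] + rng.normal(0.0, noise.joint_noise_sd, (n, 3))
    return SkeletonTrial(fs=fs, joints=joints, device="skeleton", **ids)


def default_anthropometry() -> Anthropometry:
    """Package-default segment lengths for an average adult male."""
    return Anthropometry()


def sample_anthropometry(rng: np.random.Generator, cv: float = 0.06) -> Anthropometry:
    """Draw subject anthropometry around the defaults (coefficient of variation ``cv``)."""
    base = Anthropometry()
    draw = {
        f: max(getattr(base, f) * (1.0 + rng.normal(0.0, cv)), 0.05)
        for f in ("upper_arm_length", "forearm_length", "shoulder_width", "torso_height")
    }
    return Anthropometry(**draw)
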