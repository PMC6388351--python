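"""Core domain containers.

Conventions used throughout the package
---------------------------------------
* Subject-fixed world axes: X anterior, Y up (cranial), Z to the subject's
  right (lateral).  Positions in metres, time in seconds, angles in degrees.
* Four angle channels, always in this order:
  ``shoulder_fe`` (flexion +, extension −), ``shoulder_aa`` (adduction +,
  abduction −), ``shoulder_ie`` (internal +, external −), ``elbow_fe``
  (0° = full extension).
* Rotation matrices store unit axes as *columns* (X, Y, Z), right handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import ConfigurationError, DomainError, MissingMarkerError

#: Angle channel names, fixed order used by every (T, 4) angle array.
CHANNELS: tuple[str, ...] = ("shoulder_fe", "shoulder_aa", "shoulder_ie", "elbow_fe")

#: Markers required in every marker trial (torso, shoulder, clusters).
REQUIRED_MARKERS: tuple[str, ...] = (
    "C7", "T10", "CLAV", "STRN", "ASH", "PSH",
    "PUA1", "PUA2", "PUA3", "DUA1", "DUA2", "DUA3",
)

#: Removable landmarks: present on the static trial, reconstructed dynamically.
CAST_LANDMARK_MARKERS: tuple[str, ...] = ("EL", "EM", "RS", "US")

#: Skeleton joints required by the depth-camera kinematic model.
REQUIRED_JOINTS: tuple[str, ...] = (
    "SpineShoulder", "SpineMid", "ShoulderLeft", "ShoulderRight",
    "ElbowRight", "WristRight",
)


class Task(str, Enum):
    """The four functional reach tasks."""

    CONTRALATERAL_SHOULDER = "contralateral_shoulder"
    HAND_TO_MOUTH = "hand_to_mouth"
    COMBING_HAIR = "combing_hair"
    BACK_POCKET = "back_pocket"


def _as_channel_vector(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (4,):
        raise ConfigurationError(f"{name} must be a 4-vector (one value per channel)")
    if not np.all(np.isfinite(a)):
        raise ConfigurationError(f"{name} contains non-finite values")
    return a


@dataclass(frozen=True)
class Anthropometry:
    """Segment lengths (metres) used by the forward-kinematic renderer."""

    upper_arm_length: float = 0.30
    forearm_length: float = 0.26
    shoulder_width: float = 0.38
    torso_height: float = 0.45  # C7 to T10 distance

    def __post_init__(self) -> None:
        for name in ("upper_arm_length", "forearm_length", "shoulder_width", "torso_height"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"Anthropometry.{name} must be > 0, got {v!r}")
        if self.shoulder_width >= 2 * self.torso_height:
            raise ConfigurationError("shoulder_width must be < 2 x torso_height")


# Anatomical plausibility bounds per channel, degrees.
_ANGLE_BOUNDS = ((-180.0, 180.0), (-90.0, 90.0), (-120.0, 120.0), (0.0, 150.0))


@dataclass(frozen=True)
class TaskDefinition:
    """Start/end posture (4 channels, degrees) and duration of one task."""

    task_id: Task
    start_angles: np.ndarray
    end_angles: np.ndarray
    duration: float = 2.0

    def __post_init__(self) -> None:
        try:
            tid = Task(self.task_id)
        except ValueError as exc:
            raise ConfigurationError(f"unknown task_id {self.task_id!r}") from exc
        object.__setattr__(self, "task_id", tid)
        object.__setattr__(self, "start_angles", _as_channel_vector(self.start_angles, "start_angles"))
        object.__setattr__(self, "end_angles", _as_channel_vector(self.end_angles, "end_angles"))
        if not (self.duration > 0):
            raise DomainError(f"duration must be > 0, got {self.duration!r}")
        for angles in (self.start_angles, self.end_angles):
            for val, (lo, hi), ch in zip(angles, _ANGLE_BOUNDS, CHANNELS):
                if not (lo <= val <= hi):
                    raise ConfigurationError(
                        f"{ch} = {val} outside anatomical bounds [{lo}, {hi}]"
                    )

    @property
    def primary_channel(self) -> int:
        """Index of the channel whose extremum marks the point of target achieved.

        Elbow flexion for the two hand-to-target-on-body tasks, shoulder
        flexion/extension for the two large-excursion tasks.
        """
        if self.task_id in (Task.CONTRALATERAL_SHOULDER, Task.HAND_TO_MOUTH):
            return CHANNELS.index("elbow_fe")
        return CHANNELS.index("shoulder_fe")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections applied when rendering synthetic recordings.

    ``angle_bias``, ``angle_rom_bias`` and ``angle_noise_sd`` perturb the
    underlying joint angles of the depth-camera device before rendering.
    They emulate the systematic and trial-to-trial discrepancies of skeleton
    tracking (e.g. overestimated shoulder flexion, underestimated elbow
    flexion, compressed axial-rotation excursion):

    * ``angle_bias`` — per-channel offset (degrees) of the measured angle at
      the goal posture (test − reference at the point of target achieved);
    * ``angle_rom_bias`` — per-channel offset of the measured range of
      motion.  Together the two determine the device's rest offset
      ``bias − sign(excursion) × rom_bias``, which relaxes linearly in
      movement progress toward ``angle_bias``; with ``angle_rom_bias = 0``
      the perturbation reduces to a constant offset;
    * ``angle_noise_sd`` — SD of a smooth, seeded per-trial waveform
      perturbation (degrees).
    """

    marker_noise_sd: float = 0.0       # m, per axis, marker device
    joint_noise_sd: float = 0.0        # m, per axis, skeleton device
    skeleton_time_offset: float = 0.0  # s, skeleton stream delay
    angle_bias: np.ndarray = field(default_factory=lambda: np.zeros(4))
    angle_rom_bias: np.ndarray = field(default_factory=lambda: np.zeros(4))
    angle_noise_sd: np.ndarray = field(default_factory=lambda: np.zeros(4))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_noise_sd < 0 or self.joint_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        object.__setattr__(self, "angle_bias", _as_channel_vector(self.angle_bias, "angle_bias"))
        object.__setattr__(self, "angle_rom_bias",
                           _as_channel_vector(self.angle_rom_bias, "angle_rom_bias"))
        sd = _as_channel_vector(self.angle_noise_sd, "angle_noise_sd")
        if np.any(sd < 0):
            raise ConfigurationError("angle_noise_sd must be >= 0")
        object.__setattr__(self, "angle_noise_sd", sd)

    def with_seed(self, seed: int) -> "NoiseModel":
        return replace(self, seed=int(seed))


@dataclass
class JointAngleSeries:
    """Four angle channels versus time with a per-sample validity mask."""

    time: np.ndarray          # (T,), s, strictly increasing
    angles: np.ndarray        # (T, 4), degrees, CHANNELS order
    valid: np.ndarray = None  # (T, 4) bool; True = usable sample

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 4:
            raise DomainError("angles must have shape (T, 4)")
        if self.time.shape != (self.angles.shape[0],):
            raise DomainError("time and angles lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones_like(self.angles, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.angles.shape:
                raise DomainError("valid mask shape must match angles")

    def __len__(self) -> int:
        return self.angles.shape[0]

    def channel(self, name_or_idx) -> np.ndarray:
        idx = CHANNELS.index(name_or_idx) if isinstance(name_or_idx, str) else int(name_or_idx)
        return self.angles[:, idx]


@dataclass(frozen=True)
class GroundTruthMotion:
    """Noise-free joint-angle trajectories of one simulated trial."""

    time: np.ndarray
    angles: JointAngleSeries
    task: TaskDefinition


def _check_trajectories(trajs: dict, required: tuple[str, ...], what: str) -> int:
    if not trajs:
        raise MissingMarkerError(f"empty {what} map")
    lengths = {np.asarray(v).shape[0] for v in trajs.values()}
    if len(lengths) != 1:
        raise DomainError(f"all {what} trajectories must have equal length")
    (T,) = lengths
    if T < 2:
        raise DomainError(f"{what} trajectories need at least 2 frames")
    missing = [m for m in required if m not in trajs]
    if missing:
        raise MissingMarkerError(f"missing required {what}(s): {', '.join(missing)}")
    for name, v in trajs.items():
        a = np.asarray(v, dtype=float)
        if a.shape != (T, 3):
            raise DomainError(f"{what} {name!r} must have shape (T, 3)")
        if not np.all(np.isfinite(a)):
            raise DomainError(f"{what} {name!r} contains non-finite coordinates")
    return T


@dataclass
class MarkerTrial:
    """Marker-trajectory recording of one trial (reference device)."""

    fs: float
    trajectories: dict  # marker name -> (T, 3) positions, metres
    subject: str = "S01"
    session: int = 1
    task: str = ""
    trial: int = 1
    is_static: bool = False
    device: str = "marker"

    def __post_init__(self) -> None:
        if not (self.fs > 0):
            raise DomainError("fs must be > 0")
        self.trajectories = {k: np.asarray(v, dtype=float) for k, v in self.trajectories.items()}
        required = REQUIRED_MARKERS + (CAST_LANDMARK_MARKERS if self.is_static else ())
        self._T = _check_trajectories(self.trajectories, required, "marker")

    @property
    def n_frames(self) -> int:
        return self._T

    @property
    def time(self) -> np.ndarray:
        return np.arange(self._T) / self.fs

    def __getitem__(self, marker: str) -> np.ndarray:
        try:
            return self.trajectories[marker]
        except KeyError as exc:
            raise MissingMarkerError(f"marker {marker!r} not in trial") from exc


@dataclass
class SkeletonTrial:
    """Skeleton-joint recording of one trial (depth-camera device)."""

    fs: float
    joints: dict  # joint name -> (T, 3) positions, metres
    subject: str = "S01"
    session: int = 1
    task: str = ""
    trial: int = 1
    device: str = "skeleton"

    def __post_init__(self) -> None:
        if not (self.fs > 0):
            raise DomainError("fs must be > 0")
        self.joints = {k: np.asarray(v, dtype=float) for k, v in self.joints.items()}
        self._T = _check_trajectories(self.joints, REQUIRED_JOINTS, "joint")

    @property
    def n_frames(self) -> int:
        return self._T

    @property
    def time(self) -> np.ndarray:
        return np.arange(self._T) / self.fs

    def __getitem__(self, joint: str) -> np.ndarray:
        try:
            return self.joints[joint]
        except KeyError as exc:
            raise MissingMarkerError(f"joint {joint!r} not in trial") from exc


@dataclass
class SegmentFrameSeries:
    """Per-frame pose of a body segment: origin plus orthonormal axis matrix.

    ``rotation[t]`` has the segment's X, Y, Z unit axes as columns, expressed
    in world coordinates; right handed, det = +1.
    """

    segment: str              # 'torso' | 'upper_arm' | 'forearm'
    origin: np.ndarray        # (T, 3)
    rotation: np.ndarray      # (T, 3, 3)
    valid: np.ndarray = None  # (T,) bool; False = degenerate frame

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        T = self.origin.shape[0]
        if self.rotation.shape != (T, 3, 3):
            raise DomainError("rotation must have shape (T, 3, 3)")
        if self.valid is None:
            self.valid = np.ones(T, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return self.origin.shape[0]


@dataclass(frozen=True)
class CastCalibration:
    """Constant landmark coordinates in their marker-cluster technical frames.

    Elbow epicondyles (EL, EM) live in the upper-arm cluster (PUA) frame,
    wrist styloids (RS, US) in the forearm cluster (DUA) frame.
    """

    local_coords: dict        # landmark -> (3,) local position, metres
    cluster_of: dict          # landmark -> cluster prefix ('PUA' | 'DUA')
    residual: float = 0.0     # mean reconstruction residual on the static trial, m

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "local_coords",
            {k: np.asarray(v, dtype=float) for k, v in self.local_coords.items()},
        )
        for k, v in self.local_coords.items():
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise DomainError(f"local coordinates of {k!r} must be a finite 3-vector")


@dataclass
class WaveformPair:
    """Two synchronized, equal-length waveforms on a common sampling grid."""

    channel: str
    series_a: np.ndarray
    series_b: np.ndarray
    fs: float
    lag_applied: float = 0.0  # s; positive = b lagged behind a and was advanced

    def __post_init__(self) -> None:
        self.series_a = np.asarray(self.series_a, dtype=float)
        self.series_b = np.asarray(self.series_b, dtype=float)
        if self.series_a.shape != self.series_b.shape:
            raise DomainError("aligned series must have equal length")
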