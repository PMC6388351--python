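"""On-disk formats for trials and study data.

* Marker trials: CSV, header ``time,<MARKER>_x,<MARKER>_y,<MARKER>_z,...``,
  metres and seconds, '.' decimal separator.
* Skeleton trials: JSON lines, one object per frame:
  ``{"t": <s>, "joints": {"ShoulderRight": [x, y, z], ...}}``.
* Study configuration: YAML (or JSON) mapping.

Values are written with 12 significant digits so a write/read round trip
reproduces downstream angles to well below 1e-9 degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError
from .types import MarkerTrial, SkeletonTrial

_FMT = "%.12g"


def write_marker_trial(trial: MarkerTrial, path) -> None:
    path = Path(path)
    names = sorted(trial.trajectories)
    header = "time," + ",".join(f"{m}_{ax}" for m in names for ax in "xyz")
    cols = [trial.time[:, None]] + [trial.trajectories[m] for m in names]
    data = np.hstack(cols)
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt=_FMT)


def read_marker_trial(path, is_static: bool = False, **ids) -> MarkerTrial:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header[0] != "time":
        raise DomainError(f"{path}: first CSV column must be 'time'")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    time = data[:, 0]
    if len(time) < 2:
        raise DomainError(f"{path}: need at least 2 frames")
    dt = np.diff(time)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise DomainError(f"{path}: time column must be a uniform increasing grid")
    fs = 1.0 / dt.mean()
    trajs = {}
    for i in range(1, len(header), 3):
        name = header[i].rsplit("_", 1)[0]
        trajs[name] = data[:, i:i + 3]
    return MarkerTrial(fs=fs, trajectories=trajs, is_static=is_static, **ids)


def write_skeleton_trial(trial: SkeletonTrial, path) -> None:
    path = Path(path)
    names = sorted(trial.joints)
    with open(path, "w") as fh:
        for t_idx, t in enumerate(trial.time):
            obj = {
                "t": round(float(t), 9),
                "joints": {n: [float(f"{v:.12g}") for v in trial.joints[n][t_idx]] for n in names},
            }
            fh.write(json.dumps(obj) + "\n")


def read_skeleton_trial(path, **ids) -> SkeletonTrial:
    path = Path(path)
    times, frames = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            times.append(float(obj["t"]))
            frames.append(obj["joints"])
    if len(times) < 2:
        raise DomainError(f"{path}: need at least 2 frames")
    time = np.asarray(times)
    dt = np.diff(time)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise DomainError(f"{path}: frame times must form a uniform increasing grid")
    fs = 1.0 / dt.mean()
    names = frames[0].keys()
    joints = {n: np.array([f[n] for f in frames], dtype=float) for n in names}
    return SkeletonTrial(fs=fs, joints=joints, **ids)


def load_config_mapping(path) -> dict:
    """Read a YAML or JSON configuration file into a plain mapping."""
    path = Path(path)
    try:
        with open(path) as fh:
            if path.suffix.lower() == ".json":
                obj = json.load(fh)
            else:
                obj = yaml.safe_load(fh)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(obj, dict):
        raise ConfigurationError(f"config {path} must contain a mapping")
    return obj


def save_config_mapping(mapping: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(mapping, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(mapping, fh, sort_keys=True)
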