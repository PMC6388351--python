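"""Persisting and reloading a simulated study (trials + manifest)."""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ConfigurationError
from .io import (
    read_marker_trial,
    read_skeleton_trial,
    save_config_mapping,
    write_marker_trial,
    write_skeleton_trial,
)
from .pipeline import StudyConfig, TrialRecord


def save_study(cfg: StudyConfig, records: list[TrialRecord], out_dir) -> Path:
    """Write every trial (marker CSV, static CSV, skeleton JSONL) plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config_mapping(cfg.to_mapping(), out_dir / "config.yaml")
    manifest = []
    for rec in records:
        stem = f"S{rec.subject:02d}_sess{rec.session}_{rec.task}_trial{rec.trial}"
        files = {
            "markers": f"{stem}_markers.csv",
            "static": f"{stem}_static.csv",
            "skeleton": f"{stem}_skeleton.jsonl",
        }
        write_marker_trial(rec.marker_dynamic, out_dir / files["markers"])
        write_marker_trial(rec.marker_static, out_dir / files["static"])
        write_skeleton_trial(rec.skeleton, out_dir / files["skeleton"])
        manifest.append({"subject": rec.subject, "session": rec.session,
                         "task": rec.task, "trial": rec.trial, **files})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir


def load_study(data_dir) -> tuple[StudyConfig, list[TrialRecord]]:
    """Reload a study written by :func:`save_study`."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigurationError(f"no manifest.json in {data_dir}")
    from .io import load_config_mapping

    cfg = StudyConfig.from_mapping(load_config_mapping(data_dir / "config.yaml"))
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    records = []
    for entry in manifest:
        ids = dict(subject=f"S{entry['subject']:02d}", session=entry["session"],
                   task=entry["task"], trial=entry["trial"])
        records.append(TrialRecord(
            subject=entry["subject"], session=entry["session"],
            task=entry["task"], trial=entry["trial"],
            marker_dynamic=read_marker_trial(data_dir / entry["markers"], **ids),
            marker_static=read_marker_trial(data_dir / entry["static"], is_static=True, **ids),
            skeleton=read_skeleton_trial(data_dir / entry["skeleton"], **ids),
            task_def=None,
        ))
    return cfg, records
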