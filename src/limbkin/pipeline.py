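"""Study orchestration: simulate a two-session cohort, run the validity and
reliability analyses, and write the report tables.

The simulated study mirrors the validation protocol: a cohort of subjects
performs four functional reach tasks, at least five trials per task, in two
sessions, recorded concurrently by a marker-based reference device (100 Hz)
and a depth-camera skeleton tracker (30 Hz) whose clocks are offset by an
unknown amount.  Between-subject, between-session and between-trial
variability enter through seeded perturbations of the task start/end
postures; device error enters through the noise model (position noise plus
per-channel angle bias and smooth angle noise for the skeleton device).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import signal as sig
from .agreement import (
    ICCResult,
    cmc,
    extract_pta,
    extract_rom,
    icc_3k,
    intersession_waveform_reliability,
    paired_validity,
    rmse,
)
from .errors import ConfigurationError, PairingError
from .marker_model import cast_calibrate, joint_angles_marker
from .skeleton_model import joint_angles_skeleton
from .synthetic import (
    MARKER_FS,
    SKELETON_FS,
    generate_task_motion,
    render_markers,
    render_skeleton,
    sample_anthropometry,
)
from .tasks import default_task
from .types import CHANNELS, JointAngleSeries, NoiseModel, Task, TaskDefinition

_ANGLE_CLIP = {  # keep perturbed task endpoints inside anatomical bounds
    0: (-175.0, 175.0), 1: (-85.0, 85.0), 2: (-115.0, 115.0), 3: (2.0, 148.0),
}

#: Default per-task skeleton angle bias (degrees, device − reference) at the
#: goal posture: the systematic discrepancies of skeleton tracking, by task
#: and channel (overestimated shoulder flexion, underestimated elbow flexion).
DEFAULT_ANGLE_BIAS: dict[str, tuple[float, float, float, float]] = {
    "contralateral_shoulder": (14.0, 5.9, -4.8, -14.3),
    "hand_to_mouth": (38.3, -0.3, 15.2, -22.5),
    "combing_hair": (40.9, 1.0, 24.1, -26.0),
    "back_pocket": (1.1, -7.5, 4.6, -7.5),
}

#: Default per-task skeleton range-of-motion bias (degrees, device − reference):
#: the excursion error of skeleton tracking, most notably a strongly compressed
#: axial (internal/external) rotation range.  Together with
#: :data:`DEFAULT_ANGLE_BIAS` it fixes the device's rest offset
#: ``bias − sign(excursion) × rom_bias`` (see :func:`limbkin.render_skeleton`).
DEFAULT_ANGLE_ROM_BIAS: dict[str, tuple[float, float, float, float]] = {
    "contralateral_shoulder": (7.8, 7.9, -28.0, -6.4),
    "hand_to_mouth": (32.5, 6.0, -7.5, -13.2),
    "combing_hair": (34.0, -4.7, 12.8, -19.8),
    "back_pocket": (4.7, 6.2, -4.7, -0.3),
}

#: Default smooth per-channel angle-noise SD (degrees) of the skeleton device.
DEFAULT_ANGLE_NOISE_SD: tuple[float, float, float, float] = (3.0, 3.0, 3.0, 3.0)

#: Typical skeleton-vs-reference waveform RMSE (degrees) by task and channel
#: for the four reach tasks in healthy adults; used with
#: :func:`noise_tables_from_waveform_rmse` to calibrate a noise model whose
#: waveform discrepancies have realistic per-plane magnitudes.
REFERENCE_WAVEFORM_RMSE: dict[str, tuple[float, float, float, float]] = {
    "contralateral_shoulder": (11.04, 5.62, 13.40, 15.48),
    "hand_to_mouth": (25.61, 6.11, 1.64, 18.16),
    "combing_hair": (41.40, 12.31, 29.38, 23.75),
    "back_pocket": (7.16, 5.76, 12.36, 10.43),
}


def noise_tables_from_waveform_rmse(
    rmse_table: dict,
    bias_table: dict | None = None,
    rom_bias_table: dict | None = None,
) -> dict:
    """Calibrate the stochastic angle-noise SDs from waveform RMSE targets.

    Given per-task waveform RMSE targets ``{task: (4 values)}`` (degrees) and
    the systematic discrepancy tables (goal-posture bias and ROM bias,
    defaulting to :data:`DEFAULT_ANGLE_BIAS` and
    :data:`DEFAULT_ANGLE_ROM_BIAS`), returns an ``angle_noise_sd`` table that
    assigns to the stochastic component the portion of each RMSE target not
    already produced by the systematic offset.  The systematic offset ramps
    from the rest offset ``o = bias − sign(excursion)·rom_bias`` to ``bias``
    over the movement, so its mean square over the waveform is that of a
    linear ramp, ``(o² + o·bias + bias²)/3``, and

        ``sd = sqrt(max(RMSE² − (o² + o·bias + bias²)/3, 0))``.

    Cells whose systematic contribution alone already reaches the target get
    zero stochastic noise.
    """
    bias_table = DEFAULT_ANGLE_BIAS if bias_table is None else bias_table
    rom_bias_table = DEFAULT_ANGLE_ROM_BIAS if rom_bias_table is None else rom_bias_table
    noise = {}
    for task, vals in rmse_table.items():
        vals = np.asarray(vals, dtype=float)
        b = np.asarray(bias_table.get(task, (0.0,) * 4), dtype=float)
        r = np.asarray(rom_bias_table.get(task, (0.0,) * 4), dtype=float)
        task_def = default_task(Task(task))
        excursion = task_def.end_angles - task_def.start_angles
        sgn = np.where(np.sign(excursion) == 0, 1.0, np.sign(excursion))
        rest = b - sgn * r
        systematic_ms = (rest ** 2 + rest * b + b ** 2) / 3.0
        noise[task] = tuple(np.sqrt(np.maximum(vals ** 2 - systematic_ms, 0.0)))
    return noise


@dataclass
class StudyConfig:
    """All knobs of a simulated validation study (seed-deterministic)."""

    n_subjects: int = 10
    trials_per_task: int = 5
    sessions: int = 2
    tasks: tuple[str, ...] = tuple(t.value for t in Task)
    duration: float = 2.0
    lead_in: float = 0.5   # s of quiet standing recorded before the movement
    lead_out: float = 0.5  # s recorded after the goal posture is reached

    marker_fs: float = MARKER_FS
    skeleton_fs: float = SKELETON_FS

    # signal conditioning
    cutoff_hz: float = 6.0
    filter_order: int = 4
    resample_hz: float = 300.0
    max_lag_s: float = 2.0
    n_points: int = 101

    # statistics
    alpha: float = 0.01

    # device noise
    marker_noise_sd: float = 0.0005
    joint_noise_sd: float = 0.005
    offset_range: tuple[float, float] = (0.05, 0.4)
    angle_bias: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ANGLE_BIAS.items()})
    angle_rom_bias: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ANGLE_ROM_BIAS.items()})
    angle_noise_sd: dict = field(default_factory=lambda: {t.value: DEFAULT_ANGLE_NOISE_SD for t in Task})

    # motion variability (degrees unless noted)
    between_subject_sd: float = 6.0
    between_session_sd: float = 3.0
    within_trial_sd: float = 2.0
    variability_sd: float = 1.5
    duration_jitter_sd: float = 0.15  # s
    anthro_cv: float = 0.06

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_task < 1 or self.sessions < 1:
            raise ConfigurationError("cohort sizes must be >= 1")
        if self.marker_fs <= 0 or self.skeleton_fs <= 0 or self.resample_hz <= 0:
            raise ConfigurationError("sampling rates must be > 0")
        self.tasks = tuple(Task(t).value for t in self.tasks)
        for table_name in ("angle_bias", "angle_rom_bias", "angle_noise_sd"):
            table = getattr(self, table_name)
            if not isinstance(table, dict):
                raise ConfigurationError(f"{table_name} must map task -> 4 values")
            setattr(self, table_name,
                    {Task(k).value: tuple(float(x) for x in v) for k, v in table.items()})

    # -- serialization ------------------------------------------------------
    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["tasks"] = list(d["tasks"])
        d["offset_range"] = list(d["offset_range"])
        d["angle_bias"] = {k: list(v) for k, v in d["angle_bias"].items()}
        d["angle_rom_bias"] = {k: list(v) for k, v in d["angle_rom_bias"].items()}
        d["angle_noise_sd"] = {k: list(v) for k, v in d["angle_noise_sd"].items()}
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "offset_range" in kwargs:
            kwargs["offset_range"] = tuple(kwargs["offset_range"])
        if "tasks" in kwargs:
            kwargs["tasks"] = tuple(kwargs["tasks"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One simulated trial: both device recordings plus the ground truth."""

    subject: int
    session: int
    task: str
    trial: int
    marker_dynamic: object
    marker_static: object
    skeleton: object
    task_def: TaskDefinition
    motion: object = None  # ground truth; absent when loaded from disk


def _subject_task(cfg: StudyConfig, base: TaskDefinition, subj: int, sess: int,
                  trial: int, rng: np.random.Generator) -> TaskDefinition:
    """Task definition with subject-, session- and trial-level posture offsets."""
    subj_rng = np.random.default_rng(np.random.SeedSequence(entropy=[cfg.seed, subj, 101]))
    sess_rng = np.random.default_rng(np.random.SeedSequence(entropy=[cfg.seed, subj, sess, 102]))
    t_idx = list(Task).index(base.task_id)
    subj_off = subj_rng.normal(0.0, cfg.between_subject_sd, (len(Task), 2, 4))[t_idx]
    sess_off = sess_rng.normal(0.0, cfg.between_session_sd, (len(Task), 2, 4))[t_idx]
    trial_off = rng.normal(0.0, cfg.within_trial_sd, (2, 4))
    start = base.start_angles + subj_off[0] + sess_off[0] + trial_off[0]
    end = base.end_angles + subj_off[1] + sess_off[1] + trial_off[1]
    for c, (lo, hi) in _ANGLE_CLIP.items():
        start[c] = np.clip(start[c], lo, hi)
        end[c] = np.clip(end[c], lo, hi)
    duration = max(float(cfg.duration + rng.normal(0.0, cfg.duration_jitter_sd)), 1.0)
    return TaskDefinition(task_id=base.task_id, start_angles=start, end_angles=end,
                          duration=duration)


def simulate_trial(cfg: StudyConfig, subj: int, sess: int, task_name: str, trial: int) -> TrialRecord:
    """Deterministically simulate one trial of the study."""
    t_idx = cfg.tasks.index(task_name)
    ss = np.random.SeedSequence(entropy=[cfg.seed, subj, sess, t_idx, trial])
    rng = np.random.default_rng(ss)
    trial_seed = int(ss.generate_state(1)[0] % (2 ** 31))

    anthro_rng = np.random.default_rng(np.random.SeedSequence(entropy=[cfg.seed, subj, 100]))
    anthro = sample_anthropometry(anthro_rng, cv=cfg.anthro_cv)

    base = default_task(task_name, duration=cfg.duration)
    task_def = _subject_task(cfg, base, subj, sess, trial, rng)
    motion = generate_task_motion(task_def, fs=cfg.marker_fs, seed=trial_seed,
                                  variability_sd=cfg.variability_sd)

    offset = float(rng.uniform(*cfg.offset_range))
    noise = NoiseModel(
        marker_noise_sd=cfg.marker_noise_sd,
        joint_noise_sd=cfg.joint_noise_sd,
        skeleton_time_offset=offset,
        angle_bias=np.asarray(cfg.angle_bias.get(task_name, (0, 0, 0, 0))),
        angle_rom_bias=np.asarray(cfg.angle_rom_bias.get(task_name, (0, 0, 0, 0))),
        angle_noise_sd=np.asarray(cfg.angle_noise_sd.get(task_name, (0, 0, 0, 0))),
        seed=trial_seed,
    )
    ids = dict(subject=f"S{subj:02d}", session=sess, task=task_name, trial=trial)
    dyn, stat = render_markers(motion, anthro, noise, fs=cfg.marker_fs,
                               strip_landmarks=True, lead_in=cfg.lead_in,
                               lead_out=cfg.lead_out, **ids)
    skel = render_skeleton(motion, anthro, noise, fs=cfg.skeleton_fs,
                           lead_in=cfg.lead_in, lead_out=cfg.lead_out, **ids)
    return TrialRecord(subject=subj, session=sess, task=task_name, trial=trial,
                       marker_dynamic=dyn, marker_static=stat, skeleton=skel,
                       task_def=task_def, motion=motion)


def simulate_study(cfg: StudyConfig, sessions: tuple[int, ...] | None = None) -> list[TrialRecord]:
    """All trials of the study (or of a subset of sessions), in a fixed order."""
    sessions = sessions or tuple(range(1, cfg.sessions + 1))
    records = []
    for subj in range(1, cfg.n_subjects + 1):
        for sess in sessions:
            for task_name in cfg.tasks:
                for trial in range(1, cfg.trials_per_task + 1):
                    records.append(simulate_trial(cfg, subj, sess, task_name, trial))
    return records


# ---------------------------------------------------------------------------
# Per-trial conditioning and alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedTrial:
    """Both devices' conditioned angle series on a common, synchronized grid."""

    marker: JointAngleSeries    # reference device, resampled + aligned
    skeleton: JointAngleSeries  # test device, resampled + aligned
    lag_applied: float          # s, skeleton delay removed
    marker_norm: np.ndarray     # (4, n_points) time-normalized waveforms
    skeleton_norm: np.ndarray


def _condition(angles: np.ndarray, fs: float, cfg: StudyConfig) -> np.ndarray:
    """Unwrap, low-pass filter and upsample a (T, 4) angle array."""
    x = np.degrees(np.unwrap(np.radians(angles), axis=0))
    x = sig.lowpass(x.T, fs, cutoff=cfg.cutoff_hz, order=cfg.filter_order)
    return sig.resample_to(x, fs, cfg.resample_hz)  # (4, n)


def condition_and_align(marker_angles: JointAngleSeries,
                        skeleton_angles: JointAngleSeries,
                        cfg: StudyConfig) -> AlignedTrial:
    """Filter, upsample and synchronize the two devices' angle waveforms.

    One lag per trial is estimated on the shoulder flexion/extension channel
    (the largest-excursion channel) and applied to all four channels.
    """
    m = _condition(marker_angles.angles, 1.0 / np.diff(marker_angles.time).mean(), cfg)
    s = _condition(skeleton_angles.angles, 1.0 / np.diff(skeleton_angles.time).mean(), cfg)
    fs = cfg.resample_hz
    n_short = min(m.shape[1], s.shape[1])
    max_lag = min(cfg.max_lag_s, 0.45 * n_short / fs)
    lag = sig.estimate_lag(m[0], s[0], fs, max_lag=max_lag)
    k = int(round(lag * fs))
    if k >= 0:
        m_al, s_al = m, s[:, k:]
    else:
        m_al, s_al = m[:, -k:], s
    n = min(m_al.shape[1], s_al.shape[1])
    m_al, s_al = m_al[:, :n], s_al[:, :n]
    t = np.arange(n) / fs
    return AlignedTrial(
        marker=JointAngleSeries(time=t, angles=m_al.T),
        skeleton=JointAngleSeries(time=t, angles=s_al.T),
        lag_applied=k / fs,
        marker_norm=sig.time_normalize(m_al, cfg.n_points),
        skeleton_norm=sig.time_normalize(s_al, cfg.n_points),
    )


def analyze_trial(rec: TrialRecord, cfg: StudyConfig) -> dict:
    """Angles for both devices of one trial, conditioned and aligned."""
    calib = cast_calibrate(rec.marker_static)
    ang_m = joint_angles_marker(rec.marker_dynamic, calib)
    ang_s = joint_angles_skeleton(rec.skeleton)
    aligned = condition_and_align(ang_m, ang_s, cfg)
    base = default_task(rec.task, duration=cfg.duration)
    return {
        "aligned": aligned,
        "pta_marker": extract_pta(aligned.marker, base),
        "pta_skeleton": extract_pta(aligned.skeleton, base),
        "rom_marker": extract_rom(aligned.marker),
        "rom_skeleton": extract_rom(aligned.skeleton),
    }


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Tabular results of the validity and/or reliability analyses."""

    validity_waveform: pd.DataFrame | None = None   # per task x channel CMC/RMSE
    validity_discrete: pd.DataFrame | None = None   # PTA/ROM device means, bias, r, p
    reliability_waveform: pd.DataFrame | None = None
    reliability_icc: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tables = {
            "table3.tsv": self.validity_waveform,
            "table4.tsv": self.validity_discrete,
            "table5_waveform.tsv": self.reliability_waveform,
            "table5_icc.tsv": self.reliability_icc,
        }
        payload = {"meta": self.meta}
        for fname, df in tables.items():
            if df is None:
                continue
            df.to_csv(out_dir / fname, sep="\t", index=False, float_format="%.6g")
            payload[fname.removesuffix(".tsv")] = json.loads(df.to_json(orient="records"))
        with open(out_dir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _per_subject_means(values: dict, cfg: StudyConfig, task: str) -> np.ndarray:
    """(n_subjects, 4) subject means over trials for one measure and task."""
    out = np.full((cfg.n_subjects, 4), np.nan)
    for subj in range(1, cfg.n_subjects + 1):
        rows = [v for (s, t), v in values.items() if s == subj and t == task]
        if rows:
            out[subj - 1] = np.mean(rows, axis=0)
    return out


def run_validity(cfg: StudyConfig, records: list[TrialRecord] | None = None) -> AgreementReport:
    """Concurrent-validity analysis on session-1 data.

    Per task and channel: mean (SD) of the per-trial inter-device CMC and
    RMSE of the time-normalized waveforms, plus device means, bias, Pearson
    r and paired t-test p for the angles at the point of target achieved and
    the ranges of motion (subject means over trials, n = cohort size).
    """
    if records is None:
        records = simulate_study(cfg, sessions=(1,))
    records = [r for r in records if r.session == 1]
    if not records:
        raise PairingError("no session-1 trials available")

    per_trial = {"cmc": {}, "rmse": {}}
    pta = {"marker": {}, "skeleton": {}}
    rom = {"marker": {}, "skeleton": {}}
    lags = []
    for rec in records:
        res = analyze_trial(rec, cfg)
        al = res["aligned"]
        lags.append(al.lag_applied)
        key = (rec.subject, rec.task, rec.trial)
        cmcs, rmses = np.empty(4), np.empty(4)
        for c in range(4):
            value, flag = cmc(np.stack([al.marker_norm[c], al.skeleton_norm[c]]))
            cmcs[c] = value
            rmses[c] = rmse(al.marker_norm[c], al.skeleton_norm[c])
        per_trial["cmc"][key] = cmcs
        per_trial["rmse"][key] = rmses
        sk = (rec.subject, rec.task)
        pta["marker"].setdefault(sk, []).append(res["pta_marker"])
        pta["skeleton"].setdefault(sk, []).append(res["pta_skeleton"])
        rom["marker"].setdefault(sk, []).append(res["rom_marker"])
        rom["skeleton"].setdefault(sk, []).append(res["rom_skeleton"])

    wf_rows, disc_rows = [], []
    for task in cfg.tasks:
        task_keys = [k for k in per_trial["cmc"] if k[1] == task]
        cmc_arr = np.array([per_trial["cmc"][k] for k in task_keys])
        rmse_arr = np.array([per_trial["rmse"][k] for k in task_keys])
        for c, ch in enumerate(CHANNELS):
            wf_rows.append({
                "task": task, "channel": ch,
                "cmc_mean": cmc_arr[:, c].mean(), "cmc_sd": cmc_arr[:, c].std(ddof=1),
                "rmse_mean": rmse_arr[:, c].mean(), "rmse_sd": rmse_arr[:, c].std(ddof=1),
            })
        for measure, table in (("pta", pta), ("rom", rom)):
            sk_means = {dev: np.array([np.mean(table[dev][(s, task)], axis=0)
                                       for s in range(1, cfg.n_subjects + 1)])
                        for dev in ("marker", "skeleton")}
            for c, ch in enumerate(CHANNELS):
                pv = paired_validity(sk_means["skeleton"][:, c], sk_means["marker"][:, c],
                                     alpha=cfg.alpha)
                disc_rows.append({
                    "task": task, "channel": ch, "measure": measure,
                    "test_mean": sk_means["skeleton"][:, c].mean(),
                    "test_sd": sk_means["skeleton"][:, c].std(ddof=1),
                    "ref_mean": sk_means["marker"][:, c].mean(),
                    "ref_sd": sk_means["marker"][:, c].std(ddof=1),
                    "bias": pv.bias, "r": pv.r, "p": pv.p,
                    "significant": pv.significant,
                })

    return AgreementReport(
        validity_waveform=pd.DataFrame(wf_rows),
        validity_discrete=pd.DataFrame(disc_rows),
        meta={
            "analysis": "concurrent validity (session 1)",
            "alpha": cfg.alpha,
            "n_subjects": cfg.n_subjects,
            "trials_per_task": cfg.trials_per_task,
            "mean_lag_applied_s": float(np.mean(lags)),
            "pta_rule": "extremum of the task primary channel relative to its initial value",
            "pairing": "subject-level means over trials",
            "config": cfg.to_mapping(),
        },
    )


def run_reliability(cfg: StudyConfig, records: list[TrialRecord] | None = None) -> AgreementReport:
    """Test-retest reliability of the skeleton device across the two sessions.

    Per task and channel: between-session CMC and RMSE of the skeleton
    device's time-normalized waveforms (matched trials, per-subject, mean
    (SD) across subjects), and the average-measures ICC of the PTA angles
    and ROMs over the subjects x sessions matrix (both the consistency and
    absolute-agreement forms; the absolute-agreement form is the headline).
    """
    if cfg.sessions < 2:
        raise ConfigurationError("reliability analysis needs two sessions")
    if records is None:
        records = simulate_study(cfg, sessions=(1, 2))

    norm = {}
    pta_vals, rom_vals = {}, {}
    for rec in records:
        res = analyze_trial(rec, cfg)
        key = (rec.subject, rec.session, rec.task, rec.trial)
        norm[key] = res["aligned"].skeleton_norm
        pta_vals[key] = res["pta_skeleton"]
        rom_vals[key] = res["rom_skeleton"]

    wf_rows, icc_rows = [], []
    for task in cfg.tasks:
        subj_cmc = np.full((cfg.n_subjects, 4), np.nan)
        subj_rmse = np.full((cfg.n_subjects, 4), np.nan)
        for subj in range(1, cfg.n_subjects + 1):
            s1 = [norm.get((subj, 1, task, tr)) for tr in range(1, cfg.trials_per_task + 1)]
            s2 = [norm.get((subj, 2, task, tr)) for tr in range(1, cfg.trials_per_task + 1)]
            if any(w is None for w in s1 + s2):
                raise PairingError(f"unmatched trials for subject {subj}, task {task}")
            for c in range(4):
                value, _flag, err = intersession_waveform_reliability(
                    np.array([w[c] for w in s1]), np.array([w[c] for w in s2]))
                subj_cmc[subj - 1, c] = value
                subj_rmse[subj - 1, c] = err
        for c, ch in enumerate(CHANNELS):
            wf_rows.append({
                "task": task, "channel": ch,
                "cmc_mean": subj_cmc[:, c].mean(), "cmc_sd": subj_cmc[:, c].std(ddof=1),
                "rmse_mean": subj_rmse[:, c].mean(), "rmse_sd": subj_rmse[:, c].std(ddof=1),
            })
        for measure, vals in (("pta", pta_vals), ("rom", rom_vals)):
            for c, ch in enumerate(CHANNELS):
                matrix = np.empty((cfg.n_subjects, 2))
                for subj in range(1, cfg.n_subjects + 1):
                    for sess in (1, 2):
                        trials = [vals[(subj, sess, task, tr)][c]
                                  for tr in range(1, cfg.trials_per_task + 1)]
                        matrix[subj - 1, sess - 1] = np.mean(trials)
                res: ICCResult = icc_3k(matrix)
                icc_rows.append({
                    "task": task, "channel": ch, "measure": measure,
                    "icc": res.agreement, "icc_consistency": res.consistency,
                })

    return AgreementReport(
        reliability_waveform=pd.DataFrame(wf_rows),
        reliability_icc=pd.DataFrame(icc_rows),
        meta={
            "analysis": "test-retest reliability (skeleton device, sessions 1-2)",
            "icc_model": "two-way mixed, average measures; absolute agreement reported",
            "n_subjects": cfg.n_subjects,
            "trials_per_task": cfg.trials_per_task,
            "config": cfg.to_mapping(),
        },
    )
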