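"""Test-retest reliability of the depth-camera system across two sessions.

Simulates both sessions of the study (same subjects, new session-level
posture offsets and noise realizations), then compares the depth camera with
itself between sessions: per-subject inter-session CMC and RMSE of the
time-normalized waveforms, and the average-measures intraclass correlation
(two-way mixed; absolute agreement reported, consistency also computed) of
the PTA angles and ROMs over the subjects x sessions matrix.
"""

from limbkin import StudyConfig, run_reliability

cfg = StudyConfig(n_subjects=10, trials_per_task=5, sessions=2, seed=2024)
report = run_reliability(cfg)

pd_opts = {"float_format": lambda v: f"{v:0.3f}"}
print("between-session waveform reliability of the depth camera:")
print(report.reliability_waveform.to_string(index=False, **pd_opts))

print("\nICC of the discrete parameters (absolute agreement, average measures):")
print(report.reliability_icc.to_string(index=False, **pd_opts))

# report.write("reliability_report")  # table5_waveform.tsv, table5_icc.tsv
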