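"""Concurrent-validity study: depth camera versus marker-based reference.

Simulates a 10-subject cohort performing the four functional tasks (5 trials
each, session 1), conditions both devices' angle waveforms (6 Hz zero-phase
low-pass, upsampling to a common 300 Hz grid, cross-correlation clock
alignment, time normalization to 101 points) and computes the agreement
battery: per-channel waveform CMC and RMSE, and bias / Pearson r / paired
t-test for the angles at the point of target achieved (PTA) and the ranges
of motion.

The default device-error model encodes the characteristic discrepancies of
skeleton tracking: overestimated shoulder flexion at the goal, underestimated
elbow flexion, and a strongly compressed axial-rotation excursion.
"""

from limbkin import StudyConfig, run_validity

cfg = StudyConfig(n_subjects=10, trials_per_task=5, sessions=1, seed=2024)
report = run_validity(cfg)

pd_opts = {"float_format": lambda v: f"{v:0.3f}"}
print("waveform agreement (CMC / RMSE in degrees), session 1:")
print(report.validity_waveform.to_string(index=False, **pd_opts))

disc = report.validity_discrete
pta = disc[disc.measure == "pta"]
print("\nangles at the point of target achieved (degrees):")
cols = ["task", "channel", "test_mean", "ref_mean", "bias", "r", "p", "significant"]
print(pta[cols].to_string(index=False, **pd_opts))

print(f"\nmean device clock lag removed: {report.meta['mean_lag_applied_s']:.3f} s")

# report.write("validity_report")  # writes table3.tsv, table4.tsv, report.json
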