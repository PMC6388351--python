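"""Simulate one functional reach trial and record it with both devices.

A hand-to-mouth reach is generated as a minimum-jerk trajectory between the
task's start and goal postures, then rendered twice: as a marker-based
recording (100 Hz optical reference: torso/shoulder markers, elbow/wrist
landmarks and two rigid clusters) and as a depth-camera skeleton recording
(30 Hz, delayed clock, joint position noise and systematic angle error).
"""

import numpy as np

from limbkin import (
    Anthropometry,
    NoiseModel,
    Task,
    default_task,
    generate_task_motion,
    render_markers,
    render_skeleton,
)

task = default_task(Task.HAND_TO_MOUTH)
print(f"task: {task.task_id.value}, duration {task.duration} s")
print(f"start posture (fe, aa, ie, elbow): {np.round(task.start_angles, 1)}")
print(f"goal posture  (fe, aa, ie, elbow): {np.round(task.end_angles, 1)}")

motion = generate_task_motion(task, fs=100.0, seed=42, variability_sd=1.5)
anthro = Anthropometry()

noise = NoiseModel(
    marker_noise_sd=0.0005,          # 0.5 mm optical noise
    joint_noise_sd=0.005,            # 5 mm depth-camera joint noise
    skeleton_time_offset=0.25,       # unsynchronized device clocks
    angle_bias=np.array([0.0, 0.0, 15.2, -22.5]),      # goal-posture error
    angle_rom_bias=np.array([0.0, 0.0, -7.5, -13.2]),  # excursion error
    seed=42,
)

markers, static = render_markers(motion, anthro, noise, strip_landmarks=True,
                                 lead_in=0.5, lead_out=0.5)
skeleton = render_skeleton(motion, anthro, noise, lead_in=0.5, lead_out=0.5)

print(f"\nmarker trial: {markers.n_frames} frames at {markers.fs:.0f} Hz, "
      f"{len(markers.trajectories)} markers")
print(f"static trial: {static.n_frames} frames "
      f"(includes the removable landmarks: EL, EM, RS, US)")
print(f"skeleton trial: {skeleton.n_frames} frames at {skeleton.fs:.0f} Hz, "
      f"{len(skeleton.joints)} joints")
wrist_path = np.linalg.norm(np.diff(skeleton["WristRight"], axis=0), axis=1).sum()
print(f"wrist path length seen by the depth camera: {wrist_path:.2f} m")
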