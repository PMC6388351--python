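"""Compute the four joint-angle channels with both kinematic models.

The marker model reconstructs the removable elbow/wrist landmarks from the
rigid clusters (calibrated on the static trial), builds torso and upper-arm
anatomical frames and decomposes the shoulder rotation as intrinsic
flexion -> adduction -> internal rotation; elbow flexion comes from the
shoulder-elbow-wrist geometry.  The skeleton model does the same from the
depth camera's tracked joints.  Noise-free, the two agree to a fraction of
a degree.
"""

import numpy as np

from limbkin import (
    Anthropometry,
    CHANNELS,
    NoiseModel,
    Task,
    cast_calibrate,
    default_task,
    generate_task_motion,
    joint_angles_marker,
    joint_angles_skeleton,
    render_markers,
    render_skeleton,
)

motion = generate_task_motion(default_task(Task.CONTRALATERAL_SHOULDER),
                              fs=100.0, seed=7, variability_sd=0.0)
anthro = Anthropometry()
clean = NoiseModel(seed=7)

dynamic, static = render_markers(motion, anthro, clean, strip_landmarks=True)
skeleton = render_skeleton(motion, anthro, clean, fs=100.0)

calib = cast_calibrate(static)
print(f"cluster calibration residual: {calib.residual:.2e} m")

marker_angles = joint_angles_marker(dynamic, calib)
skeleton_angles = joint_angles_skeleton(skeleton)

truth = motion.angles.angles
print("\nnoise-free inverse-kinematics RMSE per channel (degrees):")
print(f"{'channel':>12} {'marker':>10} {'skeleton':>10}")
for c, name in enumerate(CHANNELS):
    rm = np.sqrt(np.mean((marker_angles.angles[:, c] - truth[:, c]) ** 2))
    rs = np.sqrt(np.mean((skeleton_angles.angles[:, c] - truth[:, c]) ** 2))
    print(f"{name:>12} {rm:10.2e} {rs:10.2e}")

print("\ngoal posture (last frame, degrees):")
print(f"  ground truth: {np.round(truth[-1], 2)}")
print(f"  marker model: {np.round(marker_angles.angles[-1], 2)}")
print(f"  skeleton:     {np.round(skeleton_angles.angles[-1], 2)}")
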