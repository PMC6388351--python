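"""Synthetic motion generator: profiles, rendering, noise model, determinism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from limbkin import (
    NoiseModel,
    Task,
    default_task,
    generate_task_motion,
    minimum_jerk,
    render_markers,
    render_skeleton,
    sample_anthropometry,
)
from limbkin.errors import DomainError
from limbkin.synthetic import BodyPose, angles_at


def test_minimum_jerk_endpoints():
    assert minimum_jerk(0.0) == 0.0
    assert minimum_jerk(1.0) == 1.0
    # mid-point value of 10 t^3 - 15 t^4 + 6 t^5 at t = 0.5
    assert minimum_jerk(0.5) == pytest.approx(0.5, abs=1e-15)
    assert minimum_jerk(0.25) == pytest.approx(
        10 * 0.25**3 - 15 * 0.25**4 + 6 * 0.25**5, abs=1e-15)


def test_minimum_jerk_monotone_and_clamped():
    tau = np.linspace(-0.5, 1.5, 401)
    s = minimum_jerk(tau)
    assert np.all(np.diff(s) >= 0)
    assert s[0] == 0.0 and s[-1] == 1.0


def test_motion_hits_endpoints_exactly():
    task = default_task(Task.HAND_TO_MOUTH)
    motion = generate_task_motion(task, fs=100.0, seed=1, variability_sd=1.5)
    np.testing.assert_allclose(motion.angles.angles[0], task.start_angles, atol=1e-9)
    np.testing.assert_allclose(motion.angles.angles[-1], task.end_angles, atol=1e-9)


def test_monotone_rom_equals_endpoint_span():
    task = default_task(Task.COMBING_HAIR)
    motion = generate_task_motion(task, fs=100.0, seed=1, variability_sd=0.0)
    rom = motion.angles.angles.max(axis=0) - motion.angles.angles.min(axis=0)
    np.testing.assert_allclose(rom, np.abs(task.end_angles - task.start_angles),
                               atol=1e-9)


def test_motion_determinism():
    task = default_task(Task.BACK_POCKET)
    a = generate_task_motion(task, fs=100.0, seed=9, variability_sd=1.5)
    b = generate_task_motion(task, fs=100.0, seed=9, variability_sd=1.5)
    assert np.array_equal(a.angles.angles, b.angles.angles)
    c = generate_task_motion(task, fs=100.0, seed=10, variability_sd=1.5)
    assert not np.array_equal(a.angles.angles, c.angles.angles)


def test_generate_rejects_bad_fs():
    with pytest.raises(DomainError):
        generate_task_motion(default_task(Task.BACK_POCKET), fs=0.0, seed=1)


def test_angles_at_clamps_to_span(default_motion):
    before = angles_at(default_motion, np.array([-1.0]))
    after = angles_at(default_motion, np.array([99.0]))
    np.testing.assert_allclose(before[0], default_motion.angles.angles[0], atol=1e-9)
    np.testing.assert_allclose(after[0], default_motion.angles.angles[-1], atol=1e-9)


def test_rigid_body_marker_distances(default_motion, default_anthro, quiet_noise):
    """Within-segment marker distances are constant to 1e-9 m (noise-free)."""
    dyn, _ = render_markers(default_motion, default_anthro, quiet_noise)
    segments = [("PUA1", "PUA2", "PUA3", "EL", "EM"),
                ("DUA1", "DUA2", "DUA3", "RS", "US"),
                ("C7", "T10", "CLAV", "STRN", "ASH", "PSH")]
    for seg in segments:
        for i, m1 in enumerate(seg):
            for m2 in seg[i + 1:]:
                d = np.linalg.norm(dyn[m1] - dyn[m2], axis=1)
                assert np.ptp(d) < 1e-9, (m1, m2)


def test_render_markers_deterministic(default_motion, default_anthro):
    noise = NoiseModel(marker_noise_sd=0.001, seed=5)
    d1, s1 = render_markers(default_motion, default_anthro, noise)
    d2, s2 = render_markers(default_motion, default_anthro, noise)
    for m in d1.trajectories:
        assert np.array_equal(d1[m], d2[m])
        assert np.array_equal(s1[m], s2[m])


def test_strip_landmarks(default_motion, default_anthro, quiet_noise):
    dyn, stat = render_markers(default_motion, default_anthro, quiet_noise,
                               strip_landmarks=True)
    for lm in ("EL", "EM", "RS", "US"):
        assert lm not in dyn.trajectories
        assert lm in stat.trajectories


def test_lead_in_extends_recording(default_motion, default_anthro, quiet_noise):
    dyn, _ = render_markers(default_motion, default_anthro, quiet_noise)
    dyn_led, _ = render_markers(default_motion, default_anthro, quiet_noise,
                                lead_in=0.5, lead_out=0.5)
    assert dyn_led.n_frames == dyn.n_frames + 100
    # posture is held during the lead-in
    np.testing.assert_allclose(dyn_led["PUA1"][0], dyn_led["PUA1"][40], atol=1e-12)


def test_skeleton_time_offset_delays_stream(default_motion, default_anthro):
    base = render_skeleton(default_motion, default_anthro, NoiseModel(seed=1), fs=30.0)
    offs = render_skeleton(default_motion, default_anthro,
                           NoiseModel(skeleton_time_offset=0.5, seed=1), fs=30.0)
    k = 15  # 0.5 s at 30 Hz
    assert offs.n_frames == base.n_frames + k
    np.testing.assert_allclose(offs["WristRight"][k:], base["WristRight"], atol=1e-9)


def test_constant_bias_shifts_goal_posture(default_motion, default_anthro):
    """With rom_bias = 0 the angle bias is a constant offset at the goal."""
    from limbkin import joint_angles_skeleton

    bias = np.array([14.0, 0.0, 0.0, 0.0])
    clean = render_skeleton(default_motion, default_anthro, NoiseModel(seed=2), fs=30.0)
    biased = render_skeleton(default_motion, default_anthro,
                             NoiseModel(angle_bias=bias, seed=2), fs=30.0)
    fe_clean = joint_angles_skeleton(clean).angles[-1, 0]
    fe_biased = joint_angles_skeleton(biased).angles[-1, 0]
    assert fe_biased - fe_clean == pytest.approx(14.0, abs=1e-6)


def test_rom_bias_compresses_excursion(default_motion, default_anthro):
    """ROM bias reproduces both discrepancy parameters: PTA and excursion."""
    from limbkin import joint_angles_skeleton

    bias = np.array([0.0, 0.0, -4.8, 0.0])
    rom_bias = np.array([0.0, 0.0, -28.0, 0.0])
    clean = render_skeleton(default_motion, default_anthro, NoiseModel(seed=2), fs=30.0)
    dev = render_skeleton(default_motion, default_anthro,
                          NoiseModel(angle_bias=bias, angle_rom_bias=rom_bias, seed=2),
                          fs=30.0)
    ie_clean = joint_angles_skeleton(clean).angles[:, 2]
    ie_dev = joint_angles_skeleton(dev).angles[:, 2]
    # goal-posture bias realized
    assert ie_dev[-1] - ie_clean[-1] == pytest.approx(-4.8, abs=1e-6)
    # excursion compressed by 28 degrees
    assert np.ptp(ie_dev) - np.ptp(ie_clean) == pytest.approx(-28.0, abs=0.1)


def test_angle_noise_is_smooth_and_scaled(default_motion, default_anthro):
    from limbkin.synthetic import _smooth_angle_noise

    rng = np.random.default_rng(0)
    sd = np.array([3.0, 0.0, 5.0, 1.0])
    x = _smooth_angle_noise(3000, 100.0, sd, rng)
    np.testing.assert_allclose(x.std(axis=0), sd, rtol=1e-9, atol=1e-12)
    assert np.all(x[:, 1] == 0.0)
    # smooth: successive-sample differences stay well below the channel SD
    assert np.abs(np.diff(x[:, 0])).max() < 0.5 * sd[0]


def test_body_pose_segment_lengths(default_anthro):
    pose = BodyPose(default_anthro, np.array([[30.0, -10.0, 20.0, 60.0]]))
    ua = np.linalg.norm(pose.elbow[0] - pose.shoulder)
    fa = np.linalg.norm(pose.wrist[0] - pose.elbow[0])
    assert ua == pytest.approx(default_anthro.upper_arm_length, abs=1e-12)
    assert fa == pytest.approx(default_anthro.forearm_length, abs=1e-12)


def test_sample_anthropometry_positive_and_seeded():
    a = sample_anthropometry(np.random.default_rng(3), cv=0.06)
    b = sample_anthropometry(np.random.default_rng(3), cv=0.06)
    assert a == b
    assert a.upper_arm_length > 0 and a.forearm_length > 0


@given(seed=st.integers(0, 2**31 - 1))
def test_render_determinism_property(seed, default_motion, default_anthro):
    n1 = NoiseModel(marker_noise_sd=0.0005, seed=seed)
    d1, _ = render_markers(default_motion, default_anthro, n1)
    d2, _ = render_markers(default_motion, default_anthro, n1)
    assert np.array_equal(d1["C7"], d2["C7"])
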