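"""Marker filtering, rigid-pose fitting, Cardan angles and trial handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from stsim import kinematics as K
from stsim import synth


def _traj(xyz, name="m"):
    return K.MarkerTrajectory(name, np.asarray(xyz, float))


# ---------------------------------------------------------------------------
# gap filling and filtering
# ---------------------------------------------------------------------------


def test_fill_leading_gaps_uses_first_valid_value():
    xyz = np.array([[np.nan] * 3, [np.nan] * 3, [1.0, 2.0, 3.0],
                    [1.5, 2.0, 3.0]])
    out, flagged = K.fill_leading_gaps(_traj(xyz))
    assert not flagged
    np.testing.assert_allclose(out.samples[0], [1.0, 2.0, 3.0])
    np.testing.assert_allclose(out.samples[1], [1.0, 2.0, 3.0])


def test_fill_gaps_identity_and_interior_midpoint():
    xyz = np.tile(np.arange(5.0)[:, None], (1, 3))
    out, _ = K.fill_leading_gaps(_traj(xyz))
    np.testing.assert_allclose(out.samples, xyz)
    xyz2 = xyz.copy()
    xyz2[2] = np.nan
    out2, _ = K.fill_leading_gaps(_traj(xyz2))
    np.testing.assert_allclose(out2.samples[2], (xyz[1] + xyz[3]) / 2)


def test_fill_gaps_long_interior_gap_flagged():
    n = 100
    xyz = np.ones((n, 3))
    xyz[10:60] = np.nan  # 50 frames = 0.28 s > 0.1 s limit
    out, flagged = K.fill_leading_gaps(_traj(xyz))
    assert flagged == [(10, 60)]
    assert np.isnan(out.samples[30]).all()


def test_fill_gaps_all_missing_errors():
    with pytest.raises(K.KinematicsError):
        K.fill_leading_gaps(_traj(np.full((5, 3), np.nan)))


def test_lowpass_constant_unchanged():
    out = K.lowpass_markers(_traj(np.full((50, 3), 2.5)))
    np.testing.assert_allclose(out.samples, 2.5, atol=1e-12)


def test_lowpass_attenuates_60hz():
    t = np.arange(360) / 180.0
    sig = np.sin(2 * np.pi * 60 * t)
    xyz = np.column_stack([sig, sig, sig])
    out = K.lowpass_markers(_traj(xyz))
    assert np.abs(out.samples[60:-60]).max() < 0.01


def test_lowpass_preserves_interior_ramp():
    t = np.arange(400) / 180.0
    xyz = np.column_stack([t, 2 * t, -t])
    out = K.lowpass_markers(_traj(xyz))
    mid = slice(150, 250)
    np.testing.assert_allclose(out.samples[mid], xyz[mid], rtol=1e-6,
                               atol=1e-8)


def test_lowpass_requires_filled_markers():
    xyz = np.ones((50, 3))
    xyz[0] = np.nan
    with pytest.raises(K.KinematicsError):
        K.lowpass_markers(_traj(xyz))


# ---------------------------------------------------------------------------
# rigid pose estimation
# ---------------------------------------------------------------------------


def _cluster_ref():
    return np.array([[0.05, 0.03, -0.08], [-0.03, 0.04, -0.12],
                     [0.02, -0.04, -0.16]])


def _calib(ref):
    return K.StaticCalibration(reference={"seg": (("a", "b", "c"), ref)})


def test_segment_pose_identity():
    ref = _cluster_ref()
    cluster = {n: _traj(np.tile(p, (5, 1)), n) for n, p in zip("abc", ref)}
    pose = K.segment_pose(cluster, _calib(ref), "seg")
    for i in range(5):
        np.testing.assert_allclose(pose.rotation[i], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(pose.translation[i], 0.0, atol=1e-12)


def test_segment_pose_recovers_known_rotation():
    ref = _cluster_ref()
    R = Rotation.from_euler("YXZ", [25, -10, 40], degrees=True).as_matrix()
    t = np.array([0.3, -0.1, 0.5])
    obs = (R @ ref.T).T + t
    cluster = {n: _traj(np.tile(p, (3, 1)), n) for n, p in zip("abc", obs)}
    pose = K.segment_pose(cluster, _calib(ref), "seg")
    np.testing.assert_allclose(pose.rotation[0], R, atol=1e-9)
    np.testing.assert_allclose(pose.translation[0], t, atol=1e-9)


def test_segment_pose_collinear_cluster_rejected():
    ref = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
    cluster = {n: _traj(np.tile(p, (1, 1)), n) for n, p in zip("abc", ref)}
    with pytest.raises(K.DegenerateFrameError):
        K.segment_pose(cluster, _calib(ref), "seg")


def test_segment_pose_noise_monte_carlo():
    """1 mm marker noise on a 10 cm cluster: orientation error < 3 deg in 95%
    of seeded replicates."""
    ref = np.array([[0.10, 0.0, 0.0], [0.0, 0.10, 0.0], [0.0, 0.0, 0.10]])
    rng = np.random.default_rng(42)
    n_rep = 1000
    errs = np.empty(n_rep)
    for k in range(n_rep):
        obs = ref + rng.normal(0, 0.001, size=ref.shape)
        cluster = {n: _traj(p[None, :], n) for n, p in zip("abc", obs)}
        pose = K.segment_pose(cluster, _calib(ref), "seg")
        ang = np.rad2deg(np.linalg.norm(
            Rotation.from_matrix(pose.rotation[0]).as_rotvec()))
        errs[k] = ang
    assert np.quantile(errs, 0.95) < 3.0


# ---------------------------------------------------------------------------
# Cardan decomposition
# ---------------------------------------------------------------------------


def test_cardan_identity_and_pure_y():
    assert K.cardan_yxz(np.eye(3))[:3] == pytest.approx((0, 0, 0))
    R = Rotation.from_euler("Y", 30, degrees=True).as_matrix()
    ty, tx, tz, flag = K.cardan_yxz(R)
    assert (ty, tx, tz) == pytest.approx((30, 0, 0), abs=1e-9)
    assert not flag


@given(st.floats(-89, 89), st.floats(-89, 89), st.floats(-89, 89))
@settings(max_examples=100, deadline=None)
def test_cardan_round_trip(ty, tx, tz):
    R = K.compose_cardan_yxz(ty, tx, tz)
    out = K.cardan_yxz(R)
    assert out[0] == pytest.approx(ty, abs=1e-8)
    assert out[1] == pytest.approx(tx, abs=1e-8)
    assert out[2] == pytest.approx(tz, abs=1e-8)


def test_cardan_gimbal_flagged():
    R = K.compose_cardan_yxz(20.0, 90.0, 35.0)
    ty, tx, tz, flag = K.cardan_yxz(R)
    assert flag and tz == 0.0
    assert tx == pytest.approx(90.0, abs=1e-6)


def test_cardan_rejects_non_orthogonal():
    with pytest.raises(K.KinematicsError):
        K.cardan_yxz(np.eye(3) * 1.01)


# ---------------------------------------------------------------------------
# joint angles
# ---------------------------------------------------------------------------


def _pose_series(rotmats):
    n = len(rotmats)
    return K.SegmentPoseSeries(rotation=np.asarray(rotmats),
                               translation=np.zeros((n, 3)))


def test_joint_angles_zero_for_equal_poses():
    R = Rotation.from_euler("YXZ", [10, 5, -3], degrees=True).as_matrix()
    parent = _pose_series([R] * 4)
    ja = K.joint_angles(parent, parent, joint="hip")
    np.testing.assert_allclose(ja.angles["hip"], 0.0, atol=1e-9)


def test_joint_angles_hinge_rom_matches_hip_mean():
    """A pure 53.4 deg hinge sweep about Y yields exactly that flexion ROM."""
    angles = np.linspace(0.0, 53.4, 30)
    child = _pose_series([Rotation.from_euler("Y", a, degrees=True).as_matrix()
                          for a in angles])
    parent = _pose_series([np.eye(3)] * 30)
    ja = K.joint_angles(parent, child, joint="hip")
    rom = K.range_of_motion(ja)["hip"]
    assert rom[0] == pytest.approx(53.4, abs=1e-9)
    assert rom[1] == pytest.approx(0.0, abs=1e-9)


def test_joint_angles_sign_flip_negates():
    angles = np.linspace(0, 40, 10)
    child = _pose_series([Rotation.from_euler("Y", a, degrees=True).as_matrix()
                          for a in angles])
    parent = _pose_series([np.eye(3)] * 10)
    plus = K.joint_angles(parent, child, joint="j")
    minus = K.joint_angles(parent, child,
                           sign_map={"flexion_extension": -1}, joint="j")
    np.testing.assert_allclose(minus.angles["j"][:, 0],
                               -plus.angles["j"][:, 0], atol=1e-12)


def test_joint_angles_frame_mismatch_errors():
    p = _pose_series([np.eye(3)] * 3)
    c = _pose_series([np.eye(3)] * 4)
    with pytest.raises(K.KinematicsError):
        K.joint_angles(p, c)


def test_world_rotation_equivariance(default_model, clean_trial):
    """Rotating all marker data by a fixed world rotation leaves the relative
    joint-angle series unchanged."""
    from stsim import pipeline as P
    calib = synth.static_calibration(default_model)
    Rw = Rotation.from_euler("YXZ", [17, -23, 40], degrees=True).as_matrix()
    rotated = {
        name: K.MarkerTrajectory(name, (Rw @ t.samples.T).T, rate=t.rate)
        for name, t in clean_trial.markers.items()}
    a0, _, _ = P.recover_joint_angles(clean_trial.markers, default_model,
                                      calibration=calib, lowpass=False)
    a1, _, _ = P.recover_joint_angles(rotated, default_model,
                                      calibration=calib, lowpass=False)
    for j in a0.angles:
        np.testing.assert_allclose(a1.angles[j], a0.angles[j], atol=1e-6)


# ---------------------------------------------------------------------------
# screening, normalization, averaging
# ---------------------------------------------------------------------------


def _const_series(value, n=100, joint="hip"):
    block = np.full((n, 3), float(value))
    return K.JointAngleSeries(angles={joint: block},
                              grid=np.linspace(0, 100, n),
                              grid_is_percent=True)


def test_outlier_exclusion_rule():
    base = _const_series(10.0)
    shifted = _const_series(60.0)    # +50 deg -> excluded
    borderline = _const_series(54.0)  # +44 deg -> retained
    mean = _const_series(10.0)
    retained, report = K.exclude_outlier_trials([base, shifted, borderline],
                                                mean, threshold=45.0)
    assert len(retained) == 2
    assert len(report) == 1 and report[0][0] == 1
    assert report[0][3] == pytest.approx(50.0)


def test_outlier_identical_trials_none_excluded():
    trials = [_const_series(5.0) for _ in range(4)]
    retained, report = K.exclude_outlier_trials(trials, _const_series(5.0))
    assert len(retained) == 4 and not report


def test_time_normalize_linear_and_constant():
    n = 50
    t = np.arange(n) / 180.0
    block = np.column_stack([np.linspace(0, 100, n), np.zeros(n), np.zeros(n)])
    series = K.JointAngleSeries(angles={"hip": block}, grid=t)
    out = K.time_normalize(series)
    assert out.n_frames == 100
    np.testing.assert_allclose(out.channel("hip", "flexion_extension"),
                               np.linspace(0, 100, 100), atol=1e-9)
    const = K.JointAngleSeries(angles={"hip": np.full((n, 3), 7.0)}, grid=t)
    np.testing.assert_allclose(K.time_normalize(const).angles["hip"], 7.0)


def test_time_normalize_idempotent():
    series = _const_series(3.0)
    series.angles["hip"][:, 0] = np.sin(np.linspace(0, np.pi, 100))
    once = K.time_normalize(series)
    twice = K.time_normalize(once)
    np.testing.assert_allclose(twice.angles["hip"], once.angles["hip"],
                               atol=1e-12)


def test_time_normalize_sine_interpolation_error():
    n = 60
    t = np.linspace(0, 1.0, n)
    amp = 40.0
    block = np.column_stack([amp * np.sin(2 * np.pi * t), np.zeros(n),
                             np.zeros(n)])
    series = K.JointAngleSeries(angles={"hip": block}, grid=t)
    out = K.time_normalize(series)
    truth = amp * np.sin(2 * np.pi * np.linspace(0, 1, 100))
    err = np.abs(out.channel("hip", "flexion_extension") - truth).max()
    assert err < 0.005 * amp


def test_time_normalize_bad_window_errors():
    series = _const_series(1.0)
    with pytest.raises(K.KinematicsError):
        K.time_normalize(series, start=50.0, end=10.0)


def test_ensemble_average_subject_first():
    """Two subjects at 10 and 30 deg -> mean 20, SD sqrt(200) (n-1)."""
    trials = {"s1": [_const_series(10.0)], "s2": [_const_series(30.0)]}
    avg = K.ensemble_average(trials)
    np.testing.assert_allclose(avg.angles["hip"][:, 0], 20.0)
    np.testing.assert_allclose(avg.sd["hip"][:, 0], np.sqrt(200.0))


def test_ensemble_average_unbalanced_counts_do_not_bias():
    trials = {"s1": [_const_series(10.0)] * 9, "s2": [_const_series(30.0)]}
    avg = K.ensemble_average(trials)
    np.testing.assert_allclose(avg.angles["hip"][:, 0], 20.0)


def test_rom_offset_invariant():
    a = _const_series(0.0)
    a.angles["hip"][:, 0] = np.sin(np.linspace(0, np.pi, 100)) * 20
    b = _const_series(0.0)
    b.angles["hip"][:, 0] = a.angles["hip"][:, 0] + 55.0
    assert K.range_of_motion(a)["hip"][0] == pytest.approx(
        K.range_of_motion(b)["hip"][0])
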