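"""Muscle mechanics, moment arms, calibration and scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stsim import model as M
from stsim import synth


# ---------------------------------------------------------------------------
# maximal isometric force and the architecture table
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("pcsa,expected", [
    (14.11, 423.0),   # adductor magnus
    (7.62, 229.0),    # semimembranosus
    (0.0, 0.0),
])
def test_fmax_from_pcsa(pcsa, expected):
    assert M.fmax_from_pcsa(pcsa, 300.0) == expected


def test_fmax_negative_pcsa_rejected():
    with pytest.raises(M.InvalidParameterError):
        M.fmax_from_pcsa(-1.0)


def test_zero_pennation_muscles_match_table_fmax():
    """PCSA x 300 kN/m^2 reproduces every printed zero-pennation Fmax to 1 N."""
    df = M.load_muscle_table()
    zp = df[df["pennation_deg"] == 0]
    assert len(zp) >= 10
    for _, row in zp.iterrows():
        assert abs(M.fmax_from_pcsa(row["pcsa_cm2"]) - row["fmax_N"]) <= 1.0


def test_table_ratios_match_printed_values():
    ratios = M.muscle_table_ratios(M.load_muscle_table())
    assert ratios["GMed"] == pytest.approx(1.11, abs=0.005)
    assert ratios["Add"] == pytest.approx(0.68, abs=0.005)  # AddBrev + AddMag
    assert ratios["BF"] == pytest.approx(0.65, abs=0.005)


# ---------------------------------------------------------------------------
# rigid-tendon fibre state and force
# ---------------------------------------------------------------------------


def test_fibre_state_pythagorean_case():
    # l_opt = 2 cm at 30 deg pennation: height 1 cm; projection sqrt(3)
    mu = M.MuscleParams("m", 1.0, 30.0, 100.0, l_opt=2.0,
                        tsl=10.0)
    fs = M.fibre_state((10.0 + np.sqrt(3.0)) / 100.0, mu)
    assert fs.l_fibre == pytest.approx(2.0, rel=1e-12)
    assert fs.l_norm == pytest.approx(1.0, rel=1e-12)
    assert fs.cos_pennation == pytest.approx(np.sqrt(3) / 2, rel=1e-12)


def test_fibre_state_fds_model_row():
    """The FDS model-column bookkeeping: fibre 4.66 + tendon 21.36 = MTU 26.02."""
    mu = M.MuscleParams("FDS", 37.16, 0.0, 864.0, l_opt=4.66, tsl=21.36)
    fs = M.fibre_state(0.2602, mu)
    assert fs.l_norm == pytest.approx(1.0, abs=1e-12)
    assert fs.cos_pennation == 1.0


def test_fibre_state_identity_pennation_zero():
    """l_fibre * cos + tsl reconstructs the MTU length exactly."""
    mu = M.MuscleParams("m", 1.0, 0.0, 100.0, l_opt=3.0, tsl=7.0)
    for mtu in (0.08, 0.10, 0.12):
        fs = M.fibre_state(mtu, mu)
        assert fs.l_fibre * fs.cos_pennation + mu.tsl == pytest.approx(
            mtu * 100, rel=1e-14)


@given(st.floats(5.0, 40.0), st.floats(0.5, 10.0), st.floats(0.0, 60.0))
@settings(max_examples=50, deadline=None)
def test_fibre_state_identity_with_pennation(tsl, l_opt, penn):
    mu = M.MuscleParams("m", 1.0, penn, 100.0, l_opt=l_opt, tsl=tsl)
    mtu = (tsl + l_opt * 1.1) / 100.0
    fs = M.fibre_state(mtu, mu)
    assert fs.l_fibre * fs.cos_pennation + mu.tsl == pytest.approx(
        mtu * 100, rel=1e-12)


def test_fibre_state_degenerate_raises():
    mu = M.MuscleParams("m", 1.0, 0.0, 100.0, l_opt=2.0, tsl=10.0)
    with pytest.raises(M.DegenerateFibreError):
        M.fibre_state(0.09, mu)  # below slack length, zero height


@pytest.mark.parametrize("l_norm,expected", [
    (1.0, 1.0), (0.5, 0.0), (1.5, 0.0), (1.25, 0.75), (0.75, 0.75),
    (0.3, 0.0), (2.0, 0.0),
])
def test_active_force_length_curve(l_norm, expected):
    assert M.active_force_length(l_norm) == pytest.approx(expected, abs=1e-12)


@given(st.floats(0.5, 1.5))
@settings(max_examples=50, deadline=None)
def test_active_force_length_symmetry(x):
    assert M.active_force_length(x) == pytest.approx(
        M.active_force_length(2.0 - x), abs=1e-12)


def test_muscle_force_product():
    mu = M.MuscleParams("AddMag", 14.11, 0.0, 423.0, l_opt=12.5, tsl=1.67)
    fs = M.FibreState(l_fibre=12.5, l_norm=1.0, cos_pennation=1.0)
    assert M.muscle_force(1.0, mu, fs) == pytest.approx(423.0)
    assert M.muscle_force(0.0, mu, fs) == 0.0
    mu2 = M.MuscleParams("m", 1.0, 0.0, 400.0, l_opt=2.0, tsl=1.0)
    fs2 = M.FibreState(l_fibre=2.5, l_norm=1.25, cos_pennation=1.0)
    assert M.muscle_force(0.5, mu2, fs2) == pytest.approx(150.0)
    with pytest.raises(M.InvalidParameterError):
        M.muscle_force(1.5, mu2, fs2)


# ---------------------------------------------------------------------------
# MTU length and moment arms on geometric fixtures
# ---------------------------------------------------------------------------


def _pulley_model(offset_x=0.1):
    """Two-point path crossing the ankle hinge, analytic-arm fixture."""
    segments = synth._segments()
    joints = {
        "hip": M.Joint("hip", "pelvis", "thigh", synth._HIP),
        "knee": M.Joint("knee", "thigh", "shank", (0, 0, synth._KNEE_Z)),
        "ankle": M.Joint("ankle", "shank", "foot", (0, 0, synth._ANKLE_Z)),
    }
    dofs = tuple(
        M.JointDof(j, k, enabled=(j == "ankle" and k == "flexion_extension"))
        for j in ("hip", "knee", "ankle")
        for k in ("flexion_extension", "ad_abduction", "int_ext_rotation"))
    path = M.MusclePath((
        ("shank", np.array([offset_x, 0.0, synth._ANKLE_Z + 1.0])),
        ("foot", np.array([offset_x, 0.0, -1.0])),
    ))
    mu = M.MuscleParams("pulley", 1.0, 0.0, 100.0, l_opt=5.0, tsl=100.0,
                        path=path, spanned_dofs=("ankle_fe",))
    markers = {k: (s, np.asarray(p)) for k, (s, p) in synth._MARKERS.items()}
    return M.LimbModel(segments=segments, joints=joints, dofs=dofs,
                       muscles=(mu,), markers=markers)


def test_mtu_length_straight_two_point_path():
    model = _pulley_model()
    q = np.zeros(model.n_coordinates)
    L = M.mtu_length(model, M.Posture(q), model.muscles[0])
    assert L == pytest.approx(2.0, rel=1e-12)


def test_mtu_length_same_segment_constant():
    model = _pulley_model()
    mu = model.muscles[0]
    path = M.MusclePath((("shank", (0.0, 0.0, -0.05)),
                         ("shank", (0.1, 0.0, -0.20))))
    from dataclasses import replace
    mu2 = replace(mu, path=path)
    names = model.coordinate_names
    for ang in (0.0, -0.5, -1.2):
        q = np.zeros(model.n_coordinates)
        q[names.index("ankle_fe")] = ang
        L = M.mtu_length(model, M.Posture(q), mu2)
        assert L == pytest.approx(np.hypot(0.1, 0.15), rel=1e-12)


def test_moment_arm_matches_analytic_pulley():
    """Tendon-excursion arm vs. closed-form derivative of |C(theta) - P|.

    Both path points sit at x = 0.1 either side of the hinge; the analytic
    length is L(t) = |P - C(t)| with C(t) the rotated foot-fixed point.
    """
    model = _pulley_model(offset_x=0.1)
    mu = model.muscles[0]
    names = model.coordinate_names
    idx = names.index("ankle_fe")

    p1 = np.array([0.1, 0.0, 1.0])   # shank frame, relative to the joint
    p2 = np.array([0.1, 0.0, -1.0])  # foot frame

    def analytic_arm(theta):
        c, s = np.cos(theta), np.sin(theta)
        Ry = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        d = p1 - Ry @ p2
        L = np.linalg.norm(d)
        dRy = np.array([[-s, 0, c], [0, 0, 0], [-c, 0, -s]])
        dL = -(d @ (dRy @ p2)) / L
        return -dL

    for theta in (0.0, -0.3, -0.9):
        q = np.zeros(model.n_coordinates)
        q[idx] = theta
        arm = M.moment_arm(model, M.Posture(q), mu, "ankle_fe")
        assert arm == pytest.approx(analytic_arm(theta), abs=1e-6)
    # at theta = 0 the arm is exactly the 0.1 m perpendicular offset
    q = np.zeros(model.n_coordinates)
    arm0 = M.moment_arm(model, M.Posture(q), mu, "ankle_fe")
    assert abs(abs(arm0) - 0.1) < 1e-6


def test_moment_arm_zero_for_single_segment_path():
    model = _pulley_model()
    from dataclasses import replace
    mu = replace(model.muscles[0],
                 path=M.MusclePath((("shank", (0, 0, -0.05)),
                                    ("shank", (0.1, 0, -0.2)))))
    q = np.zeros(model.n_coordinates)
    assert M.moment_arm(model, M.Posture(q), mu, "ankle_fe") == pytest.approx(
        0.0, abs=1e-9)


def test_moment_arm_disabled_dof_errors():
    model = _pulley_model()
    q = np.zeros(model.n_coordinates)
    with pytest.raises(M.ModelConsistencyError):
        M.moment_arm(model, M.Posture(q), model.muscles[0], "knee_fe")


# ---------------------------------------------------------------------------
# tendon slack length calibration
# ---------------------------------------------------------------------------


def test_tune_tsl_standing_linear_case():
    """l_opt 2 cm, standing MTU 10 cm, tsl 7 (l_norm 1.5) -> tsl 7.6 (l_norm 1.2)."""
    mu = M.MuscleParams("m", 1.0, 0.0, 100.0, l_opt=2.0, tsl=7.0)
    tuned, frac = M.tune_tsl_standing(mu, 0.10)
    assert tuned.tsl == pytest.approx(7.6, abs=1e-5)
    assert frac == pytest.approx(0.06, abs=1e-5)
    assert tuned.l_opt == mu.l_opt


def test_tune_tsl_standing_already_in_window_is_identity():
    mu = M.MuscleParams("m", 1.0, 0.0, 100.0, l_opt=2.0, tsl=8.0)
    tuned, frac = M.tune_tsl_standing(mu, 0.10)
    assert tuned is mu and frac == 0.0


def test_tune_tsl_standing_idempotent():
    mu = M.MuscleParams("m", 1.0, 15.0, 100.0, l_opt=3.0, tsl=2.0)
    once, _ = M.tune_tsl_standing(mu, 0.10)
    twice, frac2 = M.tune_tsl_standing(once, 0.10)
    assert frac2 == pytest.approx(0.0, abs=1e-7)
    assert twice.tsl == pytest.approx(once.tsl, abs=1e-5)


def test_tune_tsl_applied_to_whole_table():
    """Standing calibration over all 29 muscles reports a mean adjustment of a
    few percent of MTU length for those needing it (same order as the ~7.5%
    the original calibration reports)."""
    df = M.load_muscle_table()
    fracs = []
    for _, row in df.iterrows():
        mu = M.MuscleParams(row["abbreviation"], row["pcsa_cm2"],
                            row["pennation_deg"], float(row["fmax_N"]),
                            l_opt=row["fibre_opt_measured_cm"],
                            tsl=row["tsl_measured_cm"])
        # a standing MTU length placing the muscle 30% beyond its window
        standing = (mu.tsl + 1.3 * mu.l_opt) / 100.0
        tuned, frac = M.tune_tsl_standing(mu, standing)
        fracs.append(frac)
        ln = M.fibre_state(standing, tuned).l_norm
        assert 0.8 - 1e-5 <= ln <= 1.2 + 1e-5
    adjusted = [f for f in fracs if f > 0]
    assert adjusted and 0.0 < np.mean(adjusted) < 0.25


def test_retune_fibre_range_excursion_bound():
    """3 cm excursion centred at rest forces l_opt = excursion / (1.5 - 0.5)."""
    mu = M.MuscleParams("m", 1.0, 0.0, 100.0, l_opt=2.0, tsl=7.0)
    series = np.array([7.5, 9.0, 10.5]) / 100.0
    new, flagged = M.retune_fibre_range(mu, series)
    assert flagged
    assert new.l_opt == pytest.approx(3.0, abs=1e-6)
    assert new.tsl == pytest.approx(6.0, abs=1e-6)
    assert new.l_opt + new.tsl == pytest.approx(mu.l_opt + mu.tsl, abs=1e-9)


def test_retune_fibre_range_identity_when_in_range():
    mu = M.MuscleParams("m", 1.0, 0.0, 100.0, l_opt=2.0, tsl=7.0)
    new, flagged = M.retune_fibre_range(mu, np.array([0.09, 0.09, 0.09]))
    assert not flagged and new is mu


def test_retune_flags_short_fibre_fds():
    """The measured FDS architecture (1.16 cm fibres, 25 cm tendon) cannot
    cover a multi-centimetre excursion and must be flagged for retuning."""
    mu = M.MuscleParams("FDS", 37.16, 28.0, 864.0, l_opt=1.16, tsl=25.27)
    series = np.array([24.9, 26.4, 27.9]) / 100.0
    new, flagged = M.retune_fibre_range(mu, series)
    assert flagged
    assert new.l_opt > mu.l_opt
    assert new.l_opt + new.tsl == pytest.approx(mu.mtu_rest_length, abs=1e-9)


# ---------------------------------------------------------------------------
# subject scaling
# ---------------------------------------------------------------------------


def test_scale_model_identity(default_model):
    same = {s: default_model.segments[s].length
            for s in ("thigh", "shank", "foot")}
    scaled = M.scale_model(default_model, same)
    for name in scaled.segments:
        assert scaled.segments[name].mass == pytest.approx(
            default_model.segments[name].mass, rel=1e-12)
    for a, b in zip(scaled.muscles, default_model.muscles):
        assert a.l_opt == pytest.approx(b.l_opt, rel=1e-12)


def test_scale_model_pelvis_factor_is_mean(default_model):
    lengths = {s: default_model.segments[s].length
               for s in ("thigh", "shank", "foot")}
    subject = {"thigh": lengths["thigh"] * 1.0,
               "shank": lengths["shank"] * 1.1,
               "foot": lengths["foot"] * 1.2}
    scaled = M.scale_model(default_model, subject)
    assert scaled.segments["pelvis"].length == pytest.approx(
        default_model.segments["pelvis"].length * 1.1, rel=1e-12)
    assert scaled.segments["pelvis"].mass == pytest.approx(
        default_model.segments["pelvis"].mass * 1.1**3, rel=1e-12)


def test_scale_model_doubling_doubles_mtu_lengths(default_model):
    subject = {s: 2 * default_model.segments[s].length
               for s in ("thigh", "shank", "foot")}
    scaled = M.scale_model(default_model, subject)
    for a, b in zip(scaled.muscles, default_model.muscles):
        assert a.mtu_rest_length == pytest.approx(2 * b.mtu_rest_length,
                                                  rel=1e-12)
        assert a.l_opt / a.tsl == pytest.approx(b.l_opt / b.tsl, rel=1e-9)


def test_scale_model_missing_length_errors(default_model):
    with pytest.raises(M.InvalidParameterError):
        M.scale_model(default_model, {"thigh": 0.2, "shank": 0.2})
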