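"""Synthetic sit-to-stand (StS) trials and the default greyhound hindlimb model.

The generator emulates the empirical structure of canine StS: proximal-to-
distal joint extension (hip ~0-20 %StS, knee ~10-50 %StS, ankle ~25-60 %StS),
joint ranges of motion near the measured means (hip 53.4, knee 78.5, ankle
88.7 deg), combined hindlimb vertical ground-reaction force approaching one
body weight at ~20 %StS with a small craniad pulse at ~15 %StS, a ~0.4 m
craniad centre-of-pressure excursion, trial durations of 1.14 +/- 0.16 s, and
additive Gaussian marker/force noise.  Ground truth (noiseless angles, GRFs
and, for recovery cases, generating activations) is carried alongside the
noisy observables so every pipeline stage can be tested end to end.

The default model couples the packaged muscle-architecture table to a
four-segment chain with via-point muscle paths.  Fibre and tendon lengths are
rescaled to the model geometry preserving each muscle's fibre:tendon ratio,
then calibrated exactly as a simulation study would: tendon slack lengths are
tuned so standing normalized fibre length falls in [0.8, 1.2], and fibres of
short-fibred muscles are lengthened (conserving MTU rest length) until they
operate within [0.5, 1.5] of optimum over the default motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import model as M
from .grf import ForcePlateRecord, LimbWrench, PLATE_RATE, TARGET_RATE
from .kinematics import (ANGLE_CHANNELS, JointAngleSeries, MarkerTrajectory,
                         StaticCalibration)
from .staticopt import _capacities


@dataclass
class SynthConfig:
    """Study conditions for synthetic StS trials (angles deg, lengths m)."""

    duration: float = 1.14
    duration_jitter_sd: float = 0.16
    rate: float = TARGET_RATE
    # extension timing windows, %StS
    windows: dict = field(default_factory=lambda: {
        "hip": (0.0, 20.0), "knee": (10.0, 50.0), "ankle": (25.0, 60.0)})
    # flexion/extension range of motion, deg
    rom: dict = field(default_factory=lambda: {
        "hip": 53.4, "knee": 78.5, "ankle": 88.7})
    rom_jitter_sd: dict = field(default_factory=lambda: {
        "hip": 5.6, "knee": 10.7, "ankle": 15.7})
    # joint angle at quiet standing (end of StS), deg, extension-positive
    standing_angles: dict = field(default_factory=lambda: {
        "hip": -30.0, "knee": -40.0, "ankle": -40.0})
    # non-sagittal channel excursions, deg (ad_abduction, int_ext_rotation)
    nonsagittal_rom: dict = field(default_factory=lambda: {
        "hip": (21.8, 4.3), "knee": (29.1, 21.2), "ankle": (16.4, 15.9)})
    include_nonsagittal: bool = True
    # GRF shape (combined hindlimb), body-weight units
    grf_peak_bw: float = 1.0
    grf_peak_pct: float = 20.0
    craniad_pulse_pct: float = 15.0
    craniad_pulse_bw: float = 0.08
    crouched_share_bw: float = 0.45
    standing_share_bw: float = 0.55
    cop_excursion: float = 0.4
    # noise
    marker_noise_sd: float = 0.001
    force_noise_sd: float = 2.0
    seed: int = 0
    sigmoid_steepness: float = 14.0

    def __post_init__(self):
        for j, (a, b) in self.windows.items():
            if not (0 <= a < b <= 100):
                raise ValueError(f"invalid timing window for {j}: {(a, b)}")


@dataclass
class SynthTrial:
    """One synthetic trial: noisy observables plus ground truth."""

    config: SynthConfig
    model: M.LimbModel
    q: np.ndarray                  # (n, n_coords) ground-truth coordinates, rad/m
    angles: JointAngleSeries       # ground-truth measured-convention angles, deg
    markers: dict                  # name -> MarkerTrajectory (noisy)
    wrench: LimbWrench             # combined hindlimb GRF (noisy)
    wrench_truth: LimbWrench
    seed: int = 0
    subject: str = "synth"


# ---------------------------------------------------------------------------
# default model
# ---------------------------------------------------------------------------

_HIP = np.array([-0.06, 0.04, -0.04])   # pelvis frame
_KNEE_Z = -0.235                        # thigh frame
_ANKLE_Z = -0.25                        # shank frame
_FOOT_LEN = 0.19

# measured-convention sign map: Cardan angles of the relative rotation vs.
# extension/abduction/external-rotation-positive reported angles
SIGN_MAPS = {
    "hip": {"flexion_extension": 1.0, "ad_abduction": 1.0, "int_ext_rotation": 1.0},
    "knee": {"flexion_extension": -1.0, "ad_abduction": 1.0, "int_ext_rotation": 1.0},
    "ankle": {"flexion_extension": 1.0, "ad_abduction": 1.0, "int_ext_rotation": 1.0},
}


# Per-muscle joint crossings as (joint, target flexion/extension arm,
# target ab/adduction arm, long-axis twist) in metres.  Positive arms follow
# the reporting convention: extensor / abductor / external rotator positive.
# Each crossing becomes a pulley-style pair of via points flanking the joint
# at the lateral offset that realises the arm (standing in for the wrapping
# surfaces and retinacula of the anatomical model), so arm signs are stable
# over the deeply folded crouch postures.
_MUSCLE_GEOM = {
    # hip only
    "AddBrev":    [("hip", 0.015, -0.025, 0.0)],
    "AddMag":     [("hip", 0.030, -0.030, 0.0)],
    "GMed":       [("hip", 0.035, 0.030, 0.0)],
    "GInt":       [("hip", 0.010, 0.015, -0.012)],
    "GSup":       [("hip", 0.040, 0.025, 0.0)],
    "IP":         [("hip", -0.035, 0.000, 0.0)],
    "ObtExt":     [("hip", 0.005, -0.018, 0.015)],
    "ObtInt":     [("hip", 0.006, -0.016, 0.015)],
    "Pect":       [("hip", -0.015, -0.020, 0.0)],
    "QF":         [("hip", 0.020, -0.010, 0.012)],
    "TFL1":       [("hip", -0.030, 0.020, 0.0)],
    # hip + knee
    "BF2":        [("hip", 0.050, 0.010, 0.0), ("knee", -0.020, 0.0, 0.0)],
    "BF1":        [("hip", 0.048, 0.008, 0.0), ("knee", -0.020, 0.0, 0.0)],
    "Gra":        [("hip", 0.010, -0.030, 0.0), ("knee", -0.015, 0.0, 0.0)],
    "RF":         [("hip", -0.025, 0.005, 0.0), ("knee", 0.025, 0.0, 0.0)],
    "Sart":       [("hip", -0.030, 0.008, 0.0), ("knee", -0.010, 0.0, 0.0)],
    "Sart2":      [("hip", -0.028, 0.012, 0.0), ("knee", -0.008, 0.0, 0.0)],
    "SM":         [("hip", 0.045, -0.012, 0.0), ("knee", -0.015, 0.0, 0.0)],
    "ST":         [("hip", 0.045, -0.006, 0.0), ("knee", -0.020, 0.0, 0.0)],
    # knee only
    "VL":         [("knee", 0.025, 0.010, 0.0)],
    "VM":         [("knee", 0.025, -0.010, 0.0)],
    # knee + ankle
    "FDS":        [("knee", -0.012, 0.0, 0.0), ("ankle", 0.028, 0.0, 0.0)],
    "GasL":       [("knee", -0.014, 0.008, 0.0), ("ankle", 0.025, 0.005, 0.0)],
    "GasM":       [("knee", -0.014, -0.008, 0.0), ("ankle", 0.025, -0.005, 0.0)],
    # ankle only
    "ExtDigLat":  [("ankle", -0.010, 0.010, 0.0)],
    "ExtDigLong": [("ankle", -0.014, 0.000, 0.0)],
    "FDP":        [("ankle", 0.030, 0.000, 0.0)],
    "PerLong":    [("ankle", 0.010, 0.012, 0.0)],
    "TibCran":    [("ankle", -0.018, 0.000, 0.0)],
}

# flexion axis Y-sign per joint (the knee hinge runs opposite so the chain
# zig-zags); extensor offsets sit caudal of hip/ankle, cranial of the knee
_FE_AXIS_SIGN = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}
_PAIR_EPS = 0.015   # via-point distance either side of a joint, m
_ANCHOR = 0.09      # origin/insertion anchor distance beyond the outer joints


# joint angle (deg, extension-positive coordinate) at which each pulley pair
# is aligned: the middle of the StS sweep, so arm signs hold over the whole
# crouch-to-stand fold
_DEFAULT_MID_ANGLES = {"hip": -56.7, "knee": -79.2, "ankle": -84.4}


def _build_path(crossings, joints, mid_angles=None):
    """Via-point polyline realising the requested joint crossings.

    Child-side points are pre-rotated by the joint's mid-range angle so the
    flanking pair stays on its offset side throughout the motion.
    """
    from scipy.spatial.transform import Rotation
    mid = mid_angles or _DEFAULT_MID_ANGLES

    def child_frame(joint, p_aligned):
        axis = np.array([0.0, _FE_AXIS_SIGN[joint], 0.0])
        Rm = Rotation.from_rotvec(axis * np.deg2rad(mid[joint])).as_matrix()
        return Rm.T @ p_aligned

    pts = []
    first_joint, ox, oy, tw = crossings[0]
    jloc = joints[first_joint].location
    parent = joints[first_joint].parent
    off0 = np.array([-_FE_AXIS_SIGN[first_joint] * ox, oy + tw, 0.0])
    pts.append((parent, jloc + off0 + np.array([0.0, 0.0, _ANCHOR])))
    for joint, r_fe, r_aa, twist in crossings:
        jloc = joints[joint].location
        off = np.array([-_FE_AXIS_SIGN[joint] * r_fe, r_aa, 0.0])
        pts.append((joints[joint].parent,
                    jloc + off + np.array([0.0, twist, _PAIR_EPS])))
        pts.append((joints[joint].child,
                    child_frame(joint, off + np.array([0.0, -twist, -_PAIR_EPS]))))
    last_joint, ox, oy, tw = crossings[-1]
    offN = np.array([-_FE_AXIS_SIGN[last_joint] * ox, oy - tw, 0.0])
    pts.append((joints[last_joint].child,
                child_frame(last_joint,
                            offN + np.array([0.0, 0.0, -_PAIR_EPS - _ANCHOR]))))
    return M.MusclePath(tuple(pts))

_JOINTS_SPANNED = {"Hip": ("hip",), "Hip/Knee": ("hip", "knee"),
                   "Knee": ("knee",), "Knee/Ankle": ("knee", "ankle"),
                   "Ankle": ("ankle",)}

_MARKERS = {
    # technical clusters (>= 3 non-collinear per segment, ~8-12 cm arms)
    "PelvisC1": ("pelvis", (0.04, 0.05, 0.02)),
    "PelvisC2": ("pelvis", (-0.05, 0.06, 0.03)),
    "PelvisC3": ("pelvis", (0.00, -0.02, 0.06)),
    "ThighC1": ("thigh", (0.04, 0.05, -0.06)),
    "ThighC2": ("thigh", (-0.04, 0.05, -0.10)),
    "ThighC3": ("thigh", (0.01, 0.06, -0.16)),
    "ShankC1": ("shank", (0.03, 0.04, -0.05)),
    "ShankC2": ("shank", (-0.03, 0.04, -0.11)),
    "ShankC3": ("shank", (0.01, 0.05, -0.18)),
    "FootC1": ("foot", (0.03, 0.03, -0.05)),
    "FootC2": ("foot", (-0.03, 0.04, -0.10)),
    "FootC3": ("foot", (0.02, -0.03, -0.15)),
    # anatomical landmarks
    "Hip": ("thigh", (0.0, 0.0, 0.0)),
    "KneeL": ("thigh", (0.0, 0.035, _KNEE_Z)),
    "KneeM": ("thigh", (0.0, -0.035, _KNEE_Z)),
    "AnkleL": ("shank", (0.0, 0.030, _ANKLE_Z)),
    "AnkleM": ("shank", (0.0, -0.030, _ANKLE_Z)),
    "MTHL": ("foot", (0.0, 0.025, -_FOOT_LEN)),
    "MTHM": ("foot", (0.0, -0.025, -_FOOT_LEN)),
}


def _segments():
    def rod(m, L):
        return np.diag([m * L**2 / 12, m * L**2 / 12, m * L**2 / 60])
    return {
        "pelvis": M.Segment("pelvis", 12.0, np.array([0.02, 0.0, 0.02]),
                            np.diag([0.15, 0.20, 0.20]), 0.16),
        "thigh": M.Segment("thigh", 1.30, np.array([0.0, 0.0, _KNEE_Z / 2]),
                           rod(1.30, abs(_KNEE_Z)), abs(_KNEE_Z)),
        "shank": M.Segment("shank", 0.55, np.array([0.0, 0.0, _ANKLE_Z / 2]),
                           rod(0.55, abs(_ANKLE_Z)), abs(_ANKLE_Z)),
        "foot": M.Segment("foot", 0.25, np.array([0.0, 0.0, -_FOOT_LEN / 2]),
                          rod(0.25, _FOOT_LEN), _FOOT_LEN),
    }


def _dofs(enable_nonsagittal_distal=False):
    e = enable_nonsagittal_distal
    return (
        M.JointDof("hip", "flexion_extension", (0, 1, 0), True, (-105, 15)),
        M.JointDof("hip", "ad_abduction", (1, 0, 0), True, (-40, 40)),
        M.JointDof("hip", "int_ext_rotation", (0, 0, 1), True, (-40, 40)),
        M.JointDof("knee", "flexion_extension", (0, -1, 0), True, (-135, 10)),
        M.JointDof("knee", "ad_abduction", (1, 0, 0), e, (-40, 40)),
        M.JointDof("knee", "int_ext_rotation", (0, 0, 1), e, (-40, 40)),
        M.JointDof("ankle", "flexion_extension", (0, 1, 0), True, (-145, 10)),
        M.JointDof("ankle", "ad_abduction", (1, 0, 0), e, (-40, 40)),
        M.JointDof("ankle", "int_ext_rotation", (0, 0, 1), e, (-40, 40)),
    )


def _bare_model(enable_nonsagittal_distal=False):
    joints = {
        "hip": M.Joint("hip", "pelvis", "thigh", _HIP),
        "knee": M.Joint("knee", "thigh", "shank", (0.0, 0.0, _KNEE_Z)),
        "ankle": M.Joint("ankle", "shank", "foot", (0.0, 0.0, _ANKLE_Z)),
    }
    df = M.load_muscle_table()
    muscles = []
    for _, row in df.iterrows():
        abbr = row["abbreviation"]
        spanned = _JOINTS_SPANNED[row["joint"]]
        dof_names = tuple(f"{j}_{k}" for j in spanned for k in ("fe", "aa", "rot"))
        muscles.append(M.MuscleParams(
            name=abbr, pcsa=row["pcsa_cm2"], pennation_opt=row["pennation_deg"],
            fmax=float(row["fmax_N"]), l_opt=row["fibre_opt_model_cm"],
            tsl=row["tsl_model_cm"], path=_build_path(_MUSCLE_GEOM[abbr], joints),
            spanned_dofs=dof_names))
    markers = {k: (s, np.asarray(p, float)) for k, (s, p) in _MARKERS.items()}
    return M.LimbModel(segments=_segments(), joints=joints,
                       dofs=_dofs(enable_nonsagittal_distal),
                       muscles=tuple(muscles), markers=markers)


def joint_angles_to_q(model, angles_deg):
    """Map measured-convention joint angles (deg, dict joint -> (n, 3)) onto
    model coordinates (rad); pelvis coordinates zero."""
    some = next(iter(angles_deg.values()))
    n = len(some)
    q = np.zeros((n, model.n_coordinates))
    names = model.coordinate_names
    for j, block in angles_deg.items():
        for c, kind in enumerate(("fe", "aa", "rot")):
            name = f"{j}_{kind}"
            if name in names:
                q[:, names.index(name)] = np.deg2rad(block[:, c])
    return q


def standing_posture_q(model, cfg=None):
    cfg = cfg or SynthConfig()
    blocks = {j: np.array([[cfg.standing_angles[j], 0.0, 0.0]])
              for j in ("hip", "knee", "ankle")}
    q = joint_angles_to_q(model, blocks)[0]
    # drop pelvis so the lowest foot point touches the ground
    poses = M.forward_kinematics(model, q)
    Rf, tf = poses["foot"]
    toe = tf + Rf @ np.array([0.0, 0.0, -_FOOT_LEN])
    q[2] = -min(toe[2], tf[2])
    return q


def default_model(cfg=None, calibrate=True, enable_nonsagittal_distal=False):
    """The calibrated greyhound hindlimb model used throughout the package.

    Architecture comes from the packaged table with fibre/tendon lengths
    rescaled to the via-point geometry (constant fibre:tendon ratio), then
    standing-posture TSL tuning and fibre-range retuning are applied, exactly
    the calibration sequence a rigid-tendon StS study needs.  Deterministic.
    """
    cfg = cfg or SynthConfig()
    model = _bare_model(enable_nonsagittal_distal)
    # rescale architecture to the model geometry at the straight reference pose
    q_ref = np.zeros(model.n_coordinates)
    muscles = []
    for m, L_ref in zip(model.muscles, M._all_mtu_lengths(model, q_ref)):
        f = (L_ref * 100.0) / m.mtu_rest_length
        muscles.append(replace(m, l_opt=m.l_opt * f, tsl=m.tsl * f))
    model = model.replace_muscles(muscles)
    if not calibrate:
        return model
    # 1) standing TSL tuning into normalized fibre length [0.8, 1.2]
    q_stand = standing_posture_q(model, cfg)
    lengths = M._all_mtu_lengths(model, q_stand)
    muscles = [M.tune_tsl_standing(m, L)[0]
               for m, L in zip(model.muscles, lengths)]
    model = model.replace_muscles(muscles)
    # 2) fibre-range retuning over the default StS sweep, conserving MTU length
    angles = _angle_blocks(cfg, n=101)
    q_sweep = joint_angles_to_q(model, angles)
    series = np.array([M._all_mtu_lengths(model, q) for q in q_sweep])
    muscles = [M.retune_fibre_range(m, series[:, i])[0]
               for i, m in enumerate(model.muscles)]
    return model.replace_muscles(muscles)


CLUSTER_MARKERS = {
    "pelvis": ("PelvisC1", "PelvisC2", "PelvisC3"),
    "thigh": ("ThighC1", "ThighC2", "ThighC3"),
    "shank": ("ShankC1", "ShankC2", "ShankC3"),
    "foot": ("FootC1", "FootC2", "FootC3"),
}


def static_calibration(model, clusters=None):
    """Technical-cluster geometry per segment in the anatomical frames (the
    synthetic stand-in for a standing reference trial): anatomical markers can
    be occluded in the crouch, the rigid clusters are not."""
    clusters = clusters or CLUSTER_MARKERS
    ref = {}
    for seg in M.SEGMENT_ORDER:
        names = tuple(clusters[seg])
        pts = np.array([model.markers[n][1] for n in names])
        ref[seg] = (names, pts)
    return StaticCalibration(reference=ref)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def _sigmoid01(x, k):
    """Logistic transition rescaled to hit 0 and 1 exactly at x = 0, 1."""
    x = np.clip(x, 0.0, 1.0)
    g = 1.0 / (1.0 + np.exp(-k * (x - 0.5)))
    g0 = 1.0 / (1.0 + np.exp(k / 2))
    return (g - g0) / (1.0 - 2.0 * g0)


def _window_profile(pct, window, k):
    a, b = window
    return _sigmoid01((pct - a) / (b - a), k)


def _angle_blocks(cfg, n=None):
    """Ground-truth measured-convention angle blocks, deg, per joint."""
    if n is None:
        n = max(2, int(round(cfg.duration * cfg.rate)))
    pct = np.linspace(0.0, 100.0, n)
    blocks = {}
    for j in ("hip", "knee", "ankle"):
        stand = cfg.standing_angles[j]
        crouch = stand - cfg.rom[j]
        fe = crouch + cfg.rom[j] * _window_profile(pct, cfg.windows[j],
                                                   cfg.sigmoid_steepness)
        if cfg.include_nonsagittal and j == "hip":
            aa_rom, rot_rom = cfg.nonsagittal_rom[j]
            bump = np.sin(np.pi * pct / 100.0) ** 2
            aa = aa_rom * bump
            rot = rot_rom * bump
        else:
            aa = np.zeros(n)
            rot = np.zeros(n)
        blocks[j] = np.column_stack([fe, aa, rot])
    return blocks


def synth_joint_angles(cfg=None, n=None):
    """Noiseless joint-angle ground truth as a time-based JointAngleSeries."""
    cfg = cfg or SynthConfig()
    blocks = _angle_blocks(cfg, n)
    n = len(next(iter(blocks.values())))
    t = np.linspace(0.0, cfg.duration, n)
    return JointAngleSeries(angles=blocks, grid=t, subject="synth")


def synth_grf(cfg=None, body_mass=27.0, rng=None, n=None):
    """Combined-hindlimb ground reaction force and CoP path at the marker rate.

    Vertical force moves between the crouched and standing hindquarter weight
    shares with a peak of ``grf_peak_bw`` body weights at ``grf_peak_pct``;
    a small craniad pulse is centred at ``craniad_pulse_pct``.  Returns
    (LimbWrench truth, LimbWrench noisy, cop_x series).
    """
    cfg = cfg or SynthConfig()
    if n is None:
        n = max(2, int(round(cfg.duration * cfg.rate)))
    pct = np.linspace(0.0, 100.0, n)
    bw = body_mass * M.GRAVITY
    share = (cfg.crouched_share_bw
             + (cfg.standing_share_bw - cfg.crouched_share_bw)
             * _sigmoid01((pct - 10.0) / 50.0, cfg.sigmoid_steepness))
    bump = np.exp(-0.5 * ((pct - cfg.grf_peak_pct) / 8.0) ** 2)
    base_at_peak = np.interp(cfg.grf_peak_pct, pct, share)
    fz = (share + (cfg.grf_peak_bw - base_at_peak) * bump) * bw
    fx = cfg.craniad_pulse_bw * bw * np.exp(
        -0.5 * ((pct - cfg.craniad_pulse_pct) / 5.0) ** 2)
    truth = LimbWrench(grf=np.column_stack([fx, np.zeros(n), fz]), rate=cfg.rate)
    noisy = truth.grf.copy()
    if cfg.force_noise_sd > 0:
        rng = rng or np.random.default_rng(cfg.seed)
        noisy = noisy + rng.normal(0.0, cfg.force_noise_sd, size=noisy.shape)
    cop_x = cfg.cop_excursion * _sigmoid01((pct - 10.0) / 50.0,
                                           cfg.sigmoid_steepness)
    return truth, LimbWrench(grf=noisy, rate=cfg.rate), cop_x


def synth_plate_record(cfg=None, body_mass=27.0, rng=None, baseline=0.2,
                       offset=(1.5, -0.8, 3.0)):
    """Raw-style 1,800 Hz bilateral hindlimb plate record with an unloaded
    baseline window carrying a constant sensor offset, for exercising the
    de-mean/filter/decimate chain."""
    cfg = cfg or SynthConfig()
    truth, _, cop_x = synth_grf(cfg, body_mass, n=None)
    up = int(PLATE_RATE / cfg.rate)
    n180 = truth.n_samples
    t180 = np.arange(n180) / cfg.rate
    t1800 = np.arange(int(round(cfg.duration * PLATE_RATE))) / PLATE_RATE
    force = np.column_stack([np.interp(t1800, t180, truth.grf[:, c])
                             for c in range(3)])
    n_base = int(round(baseline * PLATE_RATE))
    ramp = np.linspace(0.0, 1.0, n_base // 2)[:, None]
    lead = np.vstack([np.zeros((n_base, 3)),
                      force[0] * np.vstack([ramp, np.ones((n_base - len(ramp), 1))])])
    force = np.vstack([lead, force]) + np.asarray(offset)
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if cfg.force_noise_sd > 0:
        force = force + rng.normal(0.0, cfg.force_noise_sd, size=force.shape)
    cop = np.zeros((len(force), 3))
    cop[2 * n_base:, 0] = np.interp(t1800, t180, cop_x)
    return ForcePlateRecord(force=force, cop=cop, plate="hindlimb",
                            rate=PLATE_RATE)


def synth_markers(model, q_series, cfg=None, rng=None, leading_gap_markers=(),
                  leading_gap_fraction=0.1):
    """Marker trajectories by forward kinematics plus i.i.d. Gaussian noise.

    ``leading_gap_markers`` get NaNs over the first ``leading_gap_fraction``
    of frames, emulating occluded foot markers in the crouched posture.
    """
    cfg = cfg or SynthConfig()
    rng = rng or np.random.default_rng(cfg.seed + 2)
    for name in leading_gap_markers:
        if name not in model.markers:
            raise M.ModelConsistencyError(f"unknown marker {name!r}")
    n = len(q_series)
    world = {name: np.empty((n, 3)) for name in model.markers}
    for i, q in enumerate(q_series):
        poses = M.forward_kinematics(model, q)
        for name, (seg, local) in model.markers.items():
            R, p = poses[seg]
            world[name][i] = p + R @ local
    out = {}
    n_gap = int(round(leading_gap_fraction * n))
    for name, xyz in world.items():
        if cfg.marker_noise_sd > 0:
            xyz = xyz + rng.normal(0.0, cfg.marker_noise_sd, size=xyz.shape)
        if name in leading_gap_markers and n_gap:
            xyz = xyz.copy()
            xyz[:n_gap] = np.nan
        out[name] = MarkerTrajectory(name, xyz, rate=cfg.rate)
    return out


def synth_trial(cfg=None, model=None, seed=None):
    """Full synthetic StS trial: ground-truth coordinates, noisy markers and
    a noisy single-plate-style combined hindlimb wrench."""
    cfg = cfg or SynthConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    model = model or default_model(cfg)
    angles = synth_joint_angles(cfg)
    q = joint_angles_to_q(model, angles.angles)
    # pelvis path: pin the lateral metatarsal head to its initial ground point
    mth_local = model.markers["MTHL"][1]
    for i in range(len(q)):
        poses = M.forward_kinematics(model, q[i])
        Rf, tf = poses["foot"]
        mth = tf + Rf @ mth_local
        if i == 0:
            q0 = standing_posture_q(model, cfg)
            # start from ground contact in the crouched pose
            anchor = np.array([mth[0], mth[1], 0.0])
        q[i, 0:3] += anchor - np.array([mth[0], mth[1], mth[2] - 0.005])
        # (markers sit ~5 mm above the plate surface)
    rng = np.random.default_rng(cfg.seed)
    markers = synth_markers(model, q, cfg, rng=rng,
                            leading_gap_markers=("MTHM",))
    truth, noisy, cop_x = synth_grf(cfg, model.body_mass, rng=rng)
    return SynthTrial(config=cfg, model=model, q=q, angles=angles,
                      markers=markers, wrench=noisy, wrench_truth=truth,
                      seed=cfg.seed)


def synth_recovery_case(model, q_series, a_star, reserve_scale=1e-3):
    """Net joint moments generated by known activations through the muscle
    model itself: tau_j(t) = sum_i r_ij(q_t) F_i(a*_i, lnorm_i(t)).

    Returns the (n, n_dofs) tau series the optimizer must redistribute.
    """
    a_star = np.atleast_2d(np.asarray(a_star, float))
    if np.any(a_star < 0) or np.any(a_star > 1):
        raise ValueError("generating activations must lie in [0, 1]")
    q_series = np.atleast_2d(np.asarray(q_series, float))
    n = len(q_series)
    if len(a_star) == 1:
        a_star = np.repeat(a_star, n, axis=0)
    taus = np.empty((n, len(model.enabled_joint_dofs)))
    for i in range(n):
        C, _, _ = _capacities(model, M.Posture(q_series[i]))
        taus[i] = C @ a_star[i]
    return taus


def hinge_fixture_model(muscle_specs, posture_deg=(-56.7, -79.2, -84.4),
                        fmax_from_capacity=None):
    """Constructed fixture: flexion/extension-only chain with custom muscles.

    ``muscle_specs`` lists (name, joint, extensor-positive arm [m]) tuples;
    each muscle gets a pulley path aligned at ``posture_deg``, zero pennation
    and fibre/tendon lengths placing it exactly at optimal length there, so
    its torque capacity is activation * arm * fmax.  With
    ``fmax_from_capacity`` (name -> Nm), fmax is back-computed from the
    measured arm, making capacities exact.  Returns (model, posture q).
    Used by recovery and closed-form solver checks.
    """
    segments = _segments()
    joints = {
        "hip": M.Joint("hip", "pelvis", "thigh", _HIP),
        "knee": M.Joint("knee", "thigh", "shank", (0.0, 0.0, _KNEE_Z)),
        "ankle": M.Joint("ankle", "shank", "foot", (0.0, 0.0, _ANKLE_Z)),
    }
    dofs = tuple(
        M.JointDof(j, k, axis=None if k != "flexion_extension"
                   else (0, _FE_AXIS_SIGN[j], 0),
                   enabled=(k == "flexion_extension"), range=(-150, 20))
        for j in ("hip", "knee", "ankle")
        for k in ("flexion_extension", "ad_abduction", "int_ext_rotation"))
    mid = dict(zip(("hip", "knee", "ankle"), posture_deg))
    muscles = []
    for name, joint, arm in muscle_specs:
        path = _build_path([(joint, arm, 0.0, 0.0)], joints, mid_angles=mid)
        muscles.append(M.MuscleParams(
            name=name, pcsa=10.0, pennation_opt=0.0, fmax=300.0,
            l_opt=5.0, tsl=1.0, path=path, spanned_dofs=(f"{joint}_fe",)))
    markers = {k: (s, np.asarray(p, float)) for k, (s, p) in _MARKERS.items()}
    model = M.LimbModel(segments=segments, joints=joints, dofs=dofs,
                        muscles=tuple(muscles), markers=markers)
    q = np.zeros(model.n_coordinates)
    names = model.coordinate_names
    for j, ang in mid.items():
        q[names.index(f"{j}_fe")] = np.deg2rad(ang)
    lengths = M._all_mtu_lengths(model, q)
    tuned = [replace(mu, l_opt=5.0, tsl=L * 100.0 - 5.0)
             for mu, L in zip(model.muscles, lengths)]
    model = model.replace_muscles(tuned)
    if fmax_from_capacity:
        arms = M.moment_arm_matrix(model, M.Posture(q))
        dnames = [d.name for d in model.enabled_joint_dofs]
        adjusted = []
        for i, mu in enumerate(model.muscles):
            r = arms[i, dnames.index(mu.spanned_dofs[0])]
            adjusted.append(replace(mu, fmax=fmax_from_capacity[mu.name] / r))
        model = model.replace_muscles(adjusted)
    return model, q


def synth_ensemble(cfg=None, n_subjects=8, n_trials=5, seed=None):
    """Seeded ensemble of per-subject angle trials (100-point %StS grid) with
    between-subject ROM and duration jitter, for screening/averaging tests."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = {}
    for s in range(n_subjects):
        rom = {j: max(5.0, rng.normal(cfg.rom[j], cfg.rom_jitter_sd[j]))
               for j in cfg.rom}
        dur = max(0.4, rng.normal(cfg.duration, cfg.duration_jitter_sd))
        trials = []
        for k in range(n_trials):
            c = replace(cfg, rom=rom, duration=dur,
                        seed=int(rng.integers(2**31 - 1)))
            blocks = _angle_blocks(c, n=100)
            noise = rng.normal(0.0, 0.5, size=(100, 3))
            blocks = {j: b + noise * 0.2 for j, b in blocks.items()}
            trials.append(JointAngleSeries(
                angles=blocks, grid=np.linspace(0, 100, 100),
                grid_is_percent=True, subject=f"dog{s}"))
        out[f"dog{s}"] = trials
    return out
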