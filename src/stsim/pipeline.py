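"""End-to-end StS analysis: markers -> joint angles -> inverse dynamics ->
static optimization, in the standard processing order.

The centre of pressure is placed on the foot midline, travelling from under
the hock toward the metatarsal heads as the foot rolls from a plantigrade to
a digitigrade posture, which is what produces the craniad CoP translation
over the movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dynamics as D
from . import grf as G
from . import kinematics as K
from . import model as M
from . import staticopt as S
from .synth import SIGN_MAPS, joint_angles_to_q, static_calibration

JOINT_PAIRS = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"),
               "ankle": ("shank", "foot")}


@dataclass
class RunResult:
    angles: K.JointAngleSeries      # measured-convention joint angles, deg
    q: np.ndarray                   # model coordinates, rad/m
    wrench: G.LimbWrench            # single-limb, with CoP
    moments: D.JointMomentSeries
    solution: S.ActivationSolution
    summary: S.ReserveSummary


def recover_joint_angles(markers, model, calibration=None, lowpass=True):
    """Marker set -> per-joint Cardan angle series plus pelvis pose series."""
    calibration = calibration or static_calibration(model)
    filled = {}
    for name, traj in markers.items():
        t, _ = K.fill_leading_gaps(traj)
        filled[name] = K.lowpass_markers(t) if lowpass else t
    poses = {seg: K.segment_pose(filled, calibration, seg)
             for seg in M.SEGMENT_ORDER}
    series = [K.joint_angles(poses[p], poses[c], sign_map=SIGN_MAPS[j], joint=j)
              for j, (p, c) in JOINT_PAIRS.items()]
    return K.merge_joint_series(series), poses, filled


def coordinates_from_poses(model, angles, pelvis_poses):
    """Model coordinate trajectory from recovered angles and the pelvis pose."""
    q = joint_angles_to_q(model, angles.angles)
    q[:, 0:3] = pelvis_poses.translation
    for i in range(len(q)):
        ty, tx, tz, _ = K.cardan_yxz(pelvis_poses.rotation[i])
        q[i, 3:6] = np.deg2rad([ty, tx, tz])
    return q


def rolling_cop(filled_markers, pct, profile=None):
    """Plate-level CoP path rolling from the hock to the metatarsal heads.

    ``pct`` is the %-of-trial grid; the roll follows ``profile`` (default: a
    smooth ramp over 10-60% of the trial, tracking foot-flat to toe-off)."""
    ank = 0.5 * (filled_markers["AnkleL"].samples
                 + filled_markers["AnkleM"].samples)
    mth = 0.5 * (filled_markers["MTHL"].samples
                 + filled_markers["MTHM"].samples)
    if profile is None:
        profile = np.clip((pct - 10.0) / 50.0, 0.0, 1.0)
    cop_x = ank[:, 0] + profile * (mth[:, 0] - ank[:, 0])
    return cop_x, ank, mth


def run_sts_analysis(markers, combined_wrench, model, rate=180.0,
                     reserve_scale=1.0, quasi_static=False, lowpass=True):
    """Full nominal analysis of one trial.

    ``markers`` is the marker dictionary, ``combined_wrench`` the processed
    combined-hindlimb LimbWrench at the marker rate.
    """
    angles, poses, filled = recover_joint_angles(markers, model, lowpass=lowpass)
    q = coordinates_from_poses(model, angles, poses["pelvis"])
    q = D.prefilter_angles(q, rate) if lowpass else q
    qd, qdd = D.derivatives(q, 1.0 / rate)

    n = len(q)
    pct = np.linspace(0.0, 100.0, n)
    limb = G.split_bilateral(G.ForcePlateRecord(
        force=combined_wrench.grf, rate=rate))
    cop_x, ank, mth = rolling_cop(filled, pct)
    limb, _ = G.compose_cop(limb, cop_x, ank, mth)

    moments = D.inverse_dynamics(model, q, qd, qdd, limb,
                                 rate=rate, quasi_static=quasi_static)
    solution = S.solve_trajectory(model, q, moments.moments,
                                  reserve_scale=reserve_scale)
    summary = S.reserve_summary(solution, moments)
    return RunResult(angles=angles, q=q, wrench=limb, moments=moments,
                     solution=solution, summary=summary)
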