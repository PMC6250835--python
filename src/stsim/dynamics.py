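"""Inverse dynamics of the pelvis->foot chain.

Net generalized forces are computed frame-by-frame from the d'Alembert /
virtual-work balance

    tau_j = sum_s [ m_s (a_s - g) . J_v(s,j) + (I_s alpha_s + w_s x I_s w_s) . J_w(s,j) ]
            - F_grf . J_p(j)

where J_v and J_w are the linear (segment COM) and angular Jacobians of each
segment with respect to the generalized coordinates and J_p is the Jacobian
of the foot material point currently at the centre of pressure.  For the
rotational joint coordinates tau_j is exactly the net joint moment about that
DOF, which pairs with tendon-excursion moment arms (r = -dL/dtheta) in the
static optimization; the six pelvis coordinates yield the residual force and
torque absorbing the unmodelled trunk and other limbs.

Joint angles are pre-filtered (zero-phase 3rd-order Butterworth, 6 Hz) before
numerical differentiation.  A quasi-static mode zeroes all velocities and
accelerations.  Sign convention: extensor, abductor and external-rotator
moments are positive; normalized moments divide by body weight times leg
length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .model import GRAVITY, LimbModel, SEGMENT_ORDER, forward_kinematics


class DynamicsError(ValueError):
    pass


@dataclass
class JointMomentSeries:
    """Per-DOF net joint moments with pelvis residuals.

    ``moments`` is (n_frames, n_dofs) in Nm for ``dof_names``;
    residual force [N] and torque [Nm] are (n_frames, 3).
    """

    dof_names: tuple
    moments: np.ndarray
    residual_force: np.ndarray
    residual_torque: np.ndarray
    time: np.ndarray
    normalized: np.ndarray | None = None
    sign_map: dict | None = None

    def dof(self, name):
        return self.moments[:, self.dof_names.index(name)]


def prefilter_angles(q_series, rate, order=3, cutoff=6.0):
    """Zero-phase Butterworth low-pass on generalized coordinates before
    differentiation."""
    q_series = np.asarray(q_series, float)
    if len(q_series) < 20:
        raise DynamicsError("series too short to filter")
    b, a = butter(order, cutoff, fs=rate)
    return filtfilt(b, a, q_series, axis=0)


def derivatives(q_series, dt):
    """(qdot, qddot) by central differences (one-sided at the ends)."""
    q_series = np.asarray(q_series, float)
    if len(q_series) < 3:
        raise DynamicsError("need >= 3 frames to differentiate")
    if dt <= 0:
        raise DynamicsError("dt must be > 0")
    qd = np.gradient(q_series, dt, axis=0)
    qdd = np.gradient(qd, dt, axis=0)
    return qd, qdd


def _vee(W):
    return np.array([W[2, 1], W[0, 2], W[1, 0]])


def _jacobians(model, q, eps=1e-6):
    """Linear (COM) and angular Jacobians of every segment at q, by central
    finite differences of the forward kinematics."""
    nc = len(q)
    poses0 = forward_kinematics(model, q)
    Jv = {s: np.zeros((3, nc)) for s in SEGMENT_ORDER}
    Jw = {s: np.zeros((3, nc)) for s in SEGMENT_ORDER}
    for j in range(nc):
        qp = q.copy(); qp[j] += eps
        qm = q.copy(); qm[j] -= eps
        pp = forward_kinematics(model, qp)
        pm = forward_kinematics(model, qm)
        for s in SEGMENT_ORDER:
            Rp, tp = pp[s]
            Rm, tm = pm[s]
            com = model.segments[s].com
            Jv[s][:, j] = ((tp + Rp @ com) - (tm + Rm @ com)) / (2 * eps)
            dR = (Rp - Rm) @ poses0[s][0].T / (2 * eps)
            Jw[s][:, j] = _vee((dR - dR.T) / 2)
    return poses0, Jv, Jw


def inverse_dynamics(model, q, qd, qdd, wrench=None, rate=180.0,
                     quasi_static=False, cop_force_threshold=5.0):
    """Net joint moments and pelvis residuals over a coordinate trajectory.

    ``q``, ``qd``, ``qdd`` are (n, n_coords) in model coordinate order;
    ``wrench`` is an optional LimbWrench time-aligned with the kinematics
    (GRF applied to the foot at the CoP).
    """
    q = np.atleast_2d(np.asarray(q, float))
    n, nc = q.shape
    if nc != model.n_coordinates:
        raise DynamicsError(f"{nc} coordinates != model's {model.n_coordinates}")
    if quasi_static:
        qd = np.zeros_like(q)
        qdd = np.zeros_like(q)
    else:
        qd = np.atleast_2d(np.asarray(qd, float))
        qdd = np.atleast_2d(np.asarray(qdd, float))
    if wrench is not None and wrench.n_samples != n:
        raise DynamicsError("wrench and kinematics are not time-aligned")
    for s in SEGMENT_ORDER:
        if model.segments[s].mass <= 0:
            raise DynamicsError(f"segment {s} has non-positive mass")

    dt = 1.0 / rate
    g = model.gravity
    segs = SEGMENT_ORDER

    frames = []
    v_com = {s: np.zeros((n, 3)) for s in segs}
    w_seg = {s: np.zeros((n, 3)) for s in segs}
    for i in range(n):
        poses, Jv, Jw = _jacobians(model, q[i])
        frames.append((poses, Jv, Jw))
        for s in segs:
            v_com[s][i] = Jv[s] @ qd[i]
            w_seg[s][i] = Jw[s] @ qd[i]
    if quasi_static or n < 3:
        a_com = {s: np.zeros((n, 3)) for s in segs}
        al_seg = {s: np.zeros((n, 3)) for s in segs}
    else:
        a_com = {s: np.gradient(v_com[s], dt, axis=0) for s in segs}
        al_seg = {s: np.gradient(w_seg[s], dt, axis=0) for s in segs}

    tau = np.zeros((n, nc))
    for i in range(n):
        poses, Jv, Jw = frames[i]
        Q = np.zeros(nc)
        for s in segs:
            seg = model.segments[s]
            R, t = poses[s]
            Iw = R @ seg.inertia @ R.T
            f_in = seg.mass * (a_com[s][i] - g)
            m_in = Iw @ al_seg[s][i] + np.cross(w_seg[s][i], Iw @ w_seg[s][i])
            Q += f_in @ Jv[s] + m_in @ Jw[s]
        if wrench is not None:
            F = wrench.grf[i]
            defined = (wrench.cop is not None
                       and wrench.cop_defined is not None
                       and bool(wrench.cop_defined[i]))
            if np.linalg.norm(F) > 0:
                if not defined and F[2] >= cop_force_threshold:
                    raise DynamicsError(
                        f"frame {i}: CoP undefined while vertical force "
                        f"{F[2]:.1f} N >= threshold")
                if defined:
                    Rf, tf = poses["foot"]
                    x_com = tf + Rf @ model.segments["foot"].com
                    rel = wrench.cop[i] - x_com
                    # point Jacobian: J_p = J_vcom + J_w x (P - com)
                    Jp = Jv["foot"] + np.column_stack(
                        [np.cross(Jw["foot"][:, j], rel) for j in range(nc)])
                    Q -= F @ Jp
        tau[i] = Q

    joint_names = tuple(d.name for d in model.enabled_joint_dofs)
    return JointMomentSeries(
        dof_names=joint_names,
        moments=tau[:, 6:],
        residual_force=tau[:, 0:3],
        residual_torque=tau[:, 3:6],
        time=np.arange(n) * dt,
    )


def apply_sign_convention(moments, sign_map):
    """Remap raw axis-projection moments onto the extensor/abductor/external-
    rotator-positive reporting convention.  ``sign_map`` maps DOF name -> +-1
    and must cover every DOF."""
    missing = [d for d in moments.dof_names if d not in sign_map]
    if missing:
        raise DynamicsError(f"sign map missing DOFs: {missing}")
    signs = np.array([float(sign_map[d]) for d in moments.dof_names])
    return replace(moments, moments=moments.moments * signs,
                   sign_map=dict(sign_map))


def normalize_moments(moments, body_mass, leg_length, g=GRAVITY):
    """Dimensionless copy: moment / (body weight * leg length)."""
    if body_mass <= 0 or leg_length <= 0:
        raise DynamicsError("body mass and leg length must be > 0")
    return replace(moments,
                   normalized=moments.moments / (body_mass * g * leg_length))
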