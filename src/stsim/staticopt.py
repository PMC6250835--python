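"""Frame-wise static optimization of muscle redundancy.

Each frame solves the strictly convex program

    min_a  sum_i a_i^2 + sum_j (reserve_j / R0)^2
    s.t.   sum_i r_ij F_i(a_i) + reserve_j = tau_j        for every joint DOF j
           0 <= a_i <= 1,    reserve free

with the rigid-tendon force F_i(a) = a * Fmax_i * f_L(lnorm_i) * cos(alpha_i)
linear in activation.  Eliminating the reserves turns this into a
box-constrained linear least-squares problem, solved exactly with BVLS.
Reserve actuators model passive, non-muscular joint support; R0 (default
1 Nm) sets how expensive they are relative to muscle effort, and the moment
balance holds to machine precision by construction because the reserve
absorbs whatever the muscles do not produce.  Pelvis residual coordinates
never enter the muscle constraint set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .model import (GRAVITY, Posture, _all_mtu_lengths, active_force_length,
                    fibre_state, moment_arm_matrix)

CAPACITY_EPS = 1e-9  # muscles below this force-scale are dropped from the QP


class StaticOptError(ValueError):
    pass


@dataclass
class FrameSolution:
    activations: np.ndarray
    forces: np.ndarray
    l_norm: np.ndarray
    reserve: np.ndarray
    objective: float
    converged: bool


@dataclass
class ActivationSolution:
    """Static-optimization output over a trajectory."""

    muscle_names: tuple
    dof_names: tuple
    activations: np.ndarray  # (n, n_muscles)
    forces: np.ndarray       # (n, n_muscles) N
    l_norm: np.ndarray       # (n, n_muscles)
    reserve: np.ndarray      # (n, n_dofs) Nm
    objective: np.ndarray    # (n,)
    flagged: np.ndarray      # (n,) bool, solver trouble
    body_weight: float | None = None

    @property
    def n_frames(self):
        return len(self.activations)

    def muscle(self, name):
        return self.muscle_names.index(name)

    def forces_bw(self):
        if not self.body_weight:
            raise StaticOptError("body weight unknown")
        return self.forces / self.body_weight


@dataclass
class ReserveSummary:
    """Cycle-average and peak reserve torques against inverse-dynamics torques.

    Percentages are computed from the unrounded series; a DOF is flagged when
    its reserve exceeds 1 Nm or 5% of the matching ID torque.
    """

    dof_names: tuple
    avg_reserve: np.ndarray
    peak_reserve: np.ndarray
    avg_id: np.ndarray
    peak_id: np.ndarray
    avg_pct: np.ndarray
    peak_pct: np.ndarray
    avg_flag: np.ndarray
    peak_flag: np.ndarray

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({
            "dof": self.dof_names,
            "avg_id_Nm": self.avg_id, "peak_id_Nm": self.peak_id,
            "avg_reserve_Nm": self.avg_reserve, "peak_reserve_Nm": self.peak_reserve,
            "avg_pct_id": self.avg_pct, "peak_pct_id": self.peak_pct,
            "avg_flag": self.avg_flag, "peak_flag": self.peak_flag,
        })


def _capacities(model, posture, step=1e-4):
    """Per-frame linear force model: returns (C, l_norm, unit_force) where
    C[j, i] = r_ij * Fmax_i * f_L * cos(alpha) is DOF j's moment per unit
    activation of muscle i."""
    dofs = model.enabled_joint_dofs
    R = moment_arm_matrix(model, posture, dofs, step=step)  # (n_m, n_dof)
    lengths = _all_mtu_lengths(model, posture)
    n_m = len(model.muscles)
    ln = np.empty(n_m)
    unit = np.empty(n_m)
    for i, m in enumerate(model.muscles):
        fs = fibre_state(lengths[i], m)
        ln[i] = fs.l_norm
        unit[i] = m.fmax * active_force_length(fs.l_norm) * fs.cos_pennation
    C = (R * unit[:, None]).T  # (n_dof, n_m)
    return C, ln, unit


def solve_frame(model, posture, tau, reserve_scale=1.0, step=1e-4):
    """Solve one frame's muscle-redundancy problem.

    ``tau`` is the net joint moment vector over the model's enabled joint
    DOFs [Nm]; ``reserve_scale`` is R0 [Nm].  Returns a FrameSolution.
    """
    tau = np.asarray(tau, float)
    dofs = model.enabled_joint_dofs
    if len(tau) != len(dofs):
        raise StaticOptError(f"tau length {len(tau)} != {len(dofs)} DOFs")
    C, ln, unit = _capacities(model, posture, step=step)
    active = unit > CAPACITY_EPS  # zero-capacity muscles stay at a = 0
    Ca = C[:, active]
    n_a = int(active.sum())
    if n_a == 0:
        a_full = np.zeros(len(model.muscles))
        reserve = tau.copy()
        obj = float(np.sum((reserve / reserve_scale) ** 2))
        return FrameSolution(a_full, np.zeros_like(a_full), ln, reserve, obj, True)
    A = np.vstack([np.eye(n_a), Ca / reserve_scale])
    b = np.concatenate([np.zeros(n_a), tau / reserve_scale])
    res = lsq_linear(A, b, bounds=(0.0, 1.0), method="bvls")
    a = np.clip(res.x, 0.0, 1.0)
    a_full = np.zeros(len(model.muscles))
    a_full[active] = a
    forces = a_full * unit
    reserve = tau - C @ a_full
    obj = float(np.sum(a_full**2) + np.sum((reserve / reserve_scale) ** 2))
    return FrameSolution(a_full, forces, ln, reserve,
                         obj, bool(res.success))


def solve_trajectory(model, q_series, tau_series, reserve_scale=1.0,
                     step=1e-4, max_flagged_fraction=0.05):
    """Independent frame-wise solves over a trajectory (no activation dynamics).

    ``q_series`` is (n, n_coords) model coordinates, ``tau_series`` is
    (n, n_joint_dofs) net moments in enabled-DOF order.
    """
    q_series = np.atleast_2d(np.asarray(q_series, float))
    tau_series = np.atleast_2d(np.asarray(tau_series, float))
    n = len(q_series)
    if len(tau_series) != n:
        raise StaticOptError("kinematics and moments are not aligned")
    n_m = len(model.muscles)
    n_d = len(model.enabled_joint_dofs)
    out = ActivationSolution(
        muscle_names=tuple(m.name for m in model.muscles),
        dof_names=tuple(d.name for d in model.enabled_joint_dofs),
        activations=np.zeros((n, n_m)), forces=np.zeros((n, n_m)),
        l_norm=np.zeros((n, n_m)), reserve=np.zeros((n, n_d)),
        objective=np.zeros(n), flagged=np.zeros(n, bool),
        body_weight=model.body_mass * GRAVITY,
    )
    for i in range(n):
        sol = solve_frame(model, Posture(q_series[i]), tau_series[i],
                          reserve_scale=reserve_scale, step=step)
        out.activations[i] = sol.activations
        out.forces[i] = sol.forces
        out.l_norm[i] = sol.l_norm
        out.reserve[i] = sol.reserve
        out.objective[i] = sol.objective
        out.flagged[i] = not sol.converged
    frac = out.flagged.mean()
    if frac > max_flagged_fraction:
        raise StaticOptError(
            f"{frac:.0%} of frames failed to converge (> {max_flagged_fraction:.0%})")
    return out


def reserve_summary(sol, id_moments, reserve_limit_nm=1.0, pct_limit=5.0):
    """Average/peak reserve torques vs. inverse-dynamics torques per DOF."""
    names = sol.dof_names
    idm = np.column_stack([id_moments.dof(d) for d in names])
    if len(idm) != sol.n_frames:
        raise StaticOptError("solution and ID series are not aligned")
    avg_res = np.mean(np.abs(sol.reserve), axis=0)
    peak_res = np.max(np.abs(sol.reserve), axis=0)
    avg_id = np.mean(np.abs(idm), axis=0)
    peak_id = np.max(np.abs(idm), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        avg_pct = np.where(avg_id > 0, 100.0 * avg_res / avg_id, np.inf)
        peak_pct = np.where(peak_id > 0, 100.0 * peak_res / peak_id, np.inf)
    return ReserveSummary(
        dof_names=names,
        avg_reserve=avg_res, peak_reserve=peak_res,
        avg_id=avg_id, peak_id=peak_id,
        avg_pct=avg_pct, peak_pct=peak_pct,
        avg_flag=(avg_res > reserve_limit_nm) | (avg_pct > pct_limit),
        peak_flag=(peak_res > reserve_limit_nm) | (peak_pct > pct_limit),
    )


def muscle_report_filter(sol, act_thresh=0.2, force_thresh_bw=0.2):
    """Muscles worth reporting: peak activation > act_thresh or peak force
    > force_thresh_bw body weights over the cycle."""
    if not sol.body_weight:
        raise StaticOptError("body weight unknown")
    peak_a = sol.activations.max(axis=0)
    peak_f = sol.forces.max(axis=0) / sol.body_weight
    keep = (peak_a > act_thresh) | (peak_f > force_thresh_bw)
    return [name for name, k in zip(sol.muscle_names, keep) if k]
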