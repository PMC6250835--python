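"""Perturbation studies around the nominal simulation.

Three families, mirroring the robustness checks a static-optimization StS
study needs: tendon slack length scaled by +/-10% across all muscles, the
non-sagittal knee/ankle rotations either fixed at zero (nominal) or driven by
their measured series, and a re-run on an alternative trial.  With a rigid
tendon, shortening the tendon directly lengthens the operating fibre, so
distal muscles with tendon-to-fibre ratios of 10 or more shift by large
fractions of optimal fibre length for small tendon changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import model as M


class SensitivityError(ValueError):
    pass


@dataclass
class SensitivityRun:
    label: str  # nominal | tsl_plus10 | tsl_minus10 | unconstrained_3d | alt_trial
    model: M.LimbModel
    solution: object          # staticopt.ActivationSolution
    summary: object           # staticopt.ReserveSummary
    provenance: dict | None = None


def perturb_tsl(model, factor, muscles=None):
    """Scale tendon slack length by (1 + factor) (uniformly by default, or
    for a named subset); optimal fibre lengths are untouched."""
    if not -0.5 <= factor <= 0.5:
        raise SensitivityError("factor must be within +/-0.5")
    out = []
    for m in model.muscles:
        if muscles is not None and m.name not in muscles:
            out.append(m)
            continue
        new_tsl = m.tsl * (1.0 + factor)
        if new_tsl < 0:
            raise SensitivityError(f"{m.name}: perturbed tsl < 0")
        out.append(replace(m, tsl=new_tsl))
    return model.replace_muscles(out)


def toggle_nonsagittal(model_factory, angles, enable):
    """Nominal vs. unconstrained distal kinematics.

    ``model_factory(enable_nonsagittal_distal=...)`` builds the limb model
    with knee/ankle non-sagittal DOFs disabled (nominal) or enabled;
    ``angles`` maps joint -> (n, 3) measured angle blocks.  Returns
    (model, angles') where nominal zeroes the knee/ankle ad/abduction and
    int/ext rotation channels and the unconstrained variant keeps them.
    """
    angles = {j: np.array(a, float) for j, a in angles.items()}
    if enable:
        for j in ("knee", "ankle"):
            if j not in angles or angles[j].shape[1] != 3:
                raise SensitivityError(f"missing 3D channels for {j}")
        model = model_factory(enable_nonsagittal_distal=True)
    else:
        for j in ("knee", "ankle"):
            if j in angles:
                angles[j][:, 1:] = 0.0
        model = model_factory(enable_nonsagittal_distal=False)
    return model, angles


def compare_runs(a, b, small_baseline=1e-3):
    """Per-muscle percent change in cycle-average and peak activation from run
    ``a`` to run ``b`` ((b-a)/a x 100); baselines below ``small_baseline``
    report absolute differences instead (flagged).  Also reports per-DOF
    reserve changes."""
    sa, sb = a.solution, b.solution
    if sa.muscle_names != sb.muscle_names:
        raise SensitivityError("runs cover different muscle sets")
    if sa.n_frames != sb.n_frames:
        raise SensitivityError("runs are on different grids")
    import pandas as pd
    rows = []
    for i, name in enumerate(sa.muscle_names):
        avg_a, avg_b = sa.activations[:, i].mean(), sb.activations[:, i].mean()
        pk_a, pk_b = sa.activations[:, i].max(), sb.activations[:, i].max()
        if avg_a < small_baseline:
            rows.append((name, np.nan, avg_b - avg_a, np.nan, pk_b - pk_a, True))
        else:
            rows.append((name, 100.0 * (avg_b - avg_a) / avg_a, np.nan,
                         100.0 * (pk_b - pk_a) / max(pk_a, small_baseline),
                         np.nan, False))
    muscle_table = pd.DataFrame(
        rows, columns=["muscle", "avg_pct_change", "avg_abs_change",
                       "peak_pct_change", "peak_abs_change", "small_baseline"])
    reserve = pd.DataFrame({
        "dof": sa.dof_names,
        "avg_abs_reserve_a": np.mean(np.abs(sa.reserve), axis=0),
        "avg_abs_reserve_b": np.mean(np.abs(sb.reserve), axis=0),
    })
    reserve["change_Nm"] = (reserve["avg_abs_reserve_b"]
                            - reserve["avg_abs_reserve_a"])
    return muscle_table, reserve


def total_reserve_magnitude(solution):
    """Cycle-summed |reserve| over all DOFs [Nm] — the scalar the TSL
    perturbations move."""
    return float(np.sum(np.abs(solution.reserve)))
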