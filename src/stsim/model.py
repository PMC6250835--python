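"""Musculoskeletal model core: limb geometry, rigid-tendon Hill muscles, moment arms.

The model is a pelvis -> thigh -> shank -> foot chain articulated by hip, knee
and ankle joints, each with up to three rotational degrees of freedom (Cardan
order: flexion/extension about Y, then ad/abduction about X, then long-axis
rotation about Z).  The pelvis floats on six coordinates.  In the reference
pose the limb is fully straightened with X pointing cranially, Y toward the
animal's left and Z vertical; all joint coordinates are zero there and joint
extension is positive.

Musculotendon units (MTUs) are polyline via-point paths with a rigid tendon:
fibre length follows from MTU length by the constant-height pennation
construction, and the active force-length curve is a symmetric parabola that
vanishes at 0.5 and 1.5 times optimal fibre length.  Architecture parameters
(PCSA, pennation, optimal fibre length, tendon slack length) are stored in cm
as conventionally tabulated; geometry is in metres, forces in newtons.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "MusclePath",
    "MuscleParams",
    "JointDof",
    "Segment",
    "Joint",
    "LimbModel",
    "Posture",
    "FibreState",
    "InvalidParameterError",
    "ModelConsistencyError",
    "DegenerateFibreError",
    "InfeasibleTuningError",
    "fmax_from_pcsa",
    "forward_kinematics",
    "mtu_length",
    "moment_arm",
    "fibre_state",
    "active_force_length",
    "muscle_force",
    "tune_tsl_standing",
    "retune_fibre_range",
    "scale_model",
    "load_muscle_table",
    "muscle_table_ratios",
    "GRAVITY",
    "SIGMA_MAX_KPA",
]

GRAVITY = 9.81  # m s^-2
SIGMA_MAX_KPA = 300.0  # maximal isometric muscle stress, kN m^-2

JOINT_ORDER = ("hip", "knee", "ankle")
DOF_KINDS = ("flexion_extension", "ad_abduction", "int_ext_rotation")
# Cardan axis per DOF kind in the parent (proximal) frame at zero rotation.
KIND_AXIS = {
    "flexion_extension": np.array([0.0, 1.0, 0.0]),
    "ad_abduction": np.array([1.0, 0.0, 0.0]),
    "int_ext_rotation": np.array([0.0, 0.0, 1.0]),
}


class InvalidParameterError(ValueError):
    """A muscle or model parameter violates its physical domain."""


class ModelConsistencyError(ValueError):
    """Model components reference each other inconsistently."""


class DegenerateFibreError(ValueError):
    """Rigid-tendon geometry has no solution (fibre would have non-positive length)."""


class InfeasibleTuningError(ValueError):
    """No admissible tendon slack length / fibre length satisfies the target window."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MusclePath:
    """Ordered via points, each a (segment name, local position [m]) pair."""

    via_points: tuple

    def __post_init__(self):
        if len(self.via_points) < 2:
            raise InvalidParameterError("a muscle path needs at least two via points")
        object.__setattr__(
            self,
            "via_points",
            tuple((seg, np.asarray(p, dtype=float)) for seg, p in self.via_points),
        )

    @property
    def segments(self):
        return tuple(seg for seg, _ in self.via_points)


@dataclass(frozen=True)
class MuscleParams:
    """Architecture of one musculotendon unit.

    pcsa in cm^2, pennation_opt in degrees, fmax in N, l_opt and tsl in cm.
    """

    name: str
    pcsa: float
    pennation_opt: float
    fmax: float
    l_opt: float
    tsl: float
    path: MusclePath | None = None
    spanned_dofs: tuple = ()

    def __post_init__(self):
        if self.pcsa < 0:
            raise InvalidParameterError(f"{self.name}: pcsa must be >= 0")
        if self.l_opt <= 0:
            raise InvalidParameterError(f"{self.name}: l_opt must be > 0")
        if self.tsl < 0:
            raise InvalidParameterError(f"{self.name}: tsl must be >= 0")
        if not 0 <= self.pennation_opt < 90:
            raise InvalidParameterError(f"{self.name}: pennation must be in [0, 90)")

    @classmethod
    def from_pcsa(cls, name, pcsa, pennation_opt, l_opt, tsl,
                  sigma_max=SIGMA_MAX_KPA, **kw):
        return cls(name=name, pcsa=pcsa, pennation_opt=pennation_opt,
                   fmax=fmax_from_pcsa(pcsa, sigma_max), l_opt=l_opt, tsl=tsl, **kw)

    @property
    def mtu_rest_length(self):
        """Optimal fibre length plus tendon slack length, cm."""
        return self.l_opt + self.tsl

    @property
    def height(self):
        """Constant muscle height h = l_opt * sin(pennation), cm."""
        return self.l_opt * np.sin(np.deg2rad(self.pennation_opt))


@dataclass(frozen=True)
class JointDof:
    joint: str
    kind: str
    axis: np.ndarray = None
    enabled: bool = True
    range: tuple = (-180.0, 180.0)

    def __post_init__(self):
        if self.joint not in JOINT_ORDER:
            raise InvalidParameterError(f"unknown joint {self.joint!r}")
        if self.kind not in DOF_KINDS:
            raise InvalidParameterError(f"unknown DOF kind {self.kind!r}")
        axis = KIND_AXIS[self.kind] if self.axis is None else np.asarray(self.axis, float)
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-9:
            raise InvalidParameterError(f"{self.name}: axis must be a unit vector")
        object.__setattr__(self, "axis", axis / n)

    @property
    def name(self):
        return f"{self.joint}_{_KIND_SHORT[self.kind]}"


_KIND_SHORT = {
    "flexion_extension": "fe",
    "ad_abduction": "aa",
    "int_ext_rotation": "rot",
}


@dataclass(frozen=True)
class Segment:
    name: str
    mass: float
    com: np.ndarray
    inertia: np.ndarray
    length: float
    density_assumed: float = 1060.0

    def __post_init__(self):
        if self.mass <= 0:
            raise InvalidParameterError(f"{self.name}: mass must be > 0")
        if self.length <= 0:
            raise InvalidParameterError(f"{self.name}: length must be > 0")
        com = np.asarray(self.com, float)
        inertia = np.asarray(self.inertia, float)
        if np.min(np.linalg.eigvalsh((inertia + inertia.T) / 2)) < -1e-12:
            raise InvalidParameterError(f"{self.name}: inertia must be PSD")
        object.__setattr__(self, "com", com)
        object.__setattr__(self, "inertia", inertia)


@dataclass(frozen=True)
class Joint:
    """Articulation between two segments; located at a fixed point in the parent frame."""

    name: str
    parent: str
    child: str
    location: np.ndarray  # joint centre, parent frame [m]

    def __post_init__(self):
        object.__setattr__(self, "location", np.asarray(self.location, float))


SEGMENT_ORDER = ("pelvis", "thigh", "shank", "foot")


@dataclass(frozen=True)
class LimbModel:
    segments: dict
    joints: dict
    dofs: tuple
    muscles: tuple
    markers: dict  # name -> (segment, local position [m])
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -GRAVITY]))
    sigma_max: float = SIGMA_MAX_KPA
    body_mass: float = 27.0
    leg_length: float = 0.616

    def __post_init__(self):
        object.__setattr__(self, "gravity", np.asarray(self.gravity, float))
        for m in self.muscles:
            if m.path is None:
                raise ModelConsistencyError(f"muscle {m.name} has no path")
            for seg in m.path.segments:
                if seg not in self.segments:
                    raise ModelConsistencyError(
                        f"muscle {m.name} references unknown segment {seg!r}")
            if not any(self.dof(d).enabled for d in m.spanned_dofs if self.has_dof(d)):
                raise ModelConsistencyError(
                    f"muscle {m.name} spans no enabled DOF")

    # -- coordinate bookkeeping ------------------------------------------------
    PELVIS_COORDS = ("pelvis_tx", "pelvis_ty", "pelvis_tz",
                     "pelvis_ry", "pelvis_rx", "pelvis_rz")

    def has_dof(self, name):
        return any(d.name == name for d in self.dofs)

    def dof(self, name):
        for d in self.dofs:
            if d.name == name:
                return d
        raise ModelConsistencyError(f"unknown DOF {name!r}")

    @property
    def enabled_joint_dofs(self):
        return tuple(d for d in self.dofs if d.enabled)

    @property
    def coordinate_names(self):
        """Pelvis free coordinates followed by enabled joint coordinates."""
        return self.PELVIS_COORDS + tuple(d.name for d in self.enabled_joint_dofs)

    @property
    def n_coordinates(self):
        return len(self.coordinate_names)

    def muscle(self, name):
        for m in self.muscles:
            if m.name == name:
                return m
        raise ModelConsistencyError(f"unknown muscle {name!r}")

    def replace_muscles(self, muscles):
        return replace(self, muscles=tuple(muscles))


@dataclass(frozen=True)
class Posture:
    """Generalized coordinates: 6 pelvis (m, rad) + enabled joint rotations (rad)."""

    q: np.ndarray
    model: LimbModel = None

    def __post_init__(self):
        q = np.asarray(self.q, float)
        object.__setattr__(self, "q", q)
        if self.model is not None:
            if len(q) != self.model.n_coordinates:
                raise ModelConsistencyError(
                    f"posture length {len(q)} != coordinate count "
                    f"{self.model.n_coordinates}")
            slack = np.deg2rad(5.0)
            for d, qi in zip(self.model.enabled_joint_dofs, q[6:]):
                lo, hi = np.deg2rad(d.range)
                if not (lo - slack <= qi <= hi + slack):
                    raise InvalidParameterError(
                        f"{d.name}={np.rad2deg(qi):.1f} deg outside declared "
                        f"range {d.range} (+/-5 deg)")

    def coordinate(self, name):
        return self.q[self.model.coordinate_names.index(name)]


@dataclass(frozen=True)
class FibreState:
    l_fibre: float  # cm
    l_norm: float
    cos_pennation: float


# ---------------------------------------------------------------------------
# muscle mechanics
# ---------------------------------------------------------------------------


def fmax_from_pcsa(pcsa, sigma_max=SIGMA_MAX_KPA):
    """Maximal isometric force [N] from PCSA [cm^2] at a stress of sigma_max [kN m^-2].

    Rounded to the nearest newton, matching how architecture tables print it.
    No pennation factor is applied.
    """
    if pcsa < 0:
        raise InvalidParameterError("pcsa must be >= 0")
    if sigma_max <= 0:
        raise InvalidParameterError("sigma_max must be > 0")
    return float(np.round(pcsa * 1e-4 * sigma_max * 1e3))


def active_force_length(l_norm):
    """Active force-length scale factor in [0, 1].

    Symmetric parabola with maximum 1 at l_norm = 1, vanishing at 0.5 and 1.5
    (the admissible fibre operating range) and zero outside.
    """
    l_norm = np.asarray(l_norm, float)
    if np.any(l_norm <= 0):
        raise InvalidParameterError("l_norm must be > 0")
    f = 1.0 - ((l_norm - 1.0) / 0.5) ** 2
    return np.maximum(0.0, f) if f.ndim else float(max(0.0, f))


def fibre_state(mtu_len, muscle):
    """Rigid-tendon fibre kinematics from MTU length [m].

    Constant-height construction: h = l_opt*sin(pennation) is fixed, the fibre
    projection onto the tendon line is p = L_mtu - tsl, and
    l_fibre = sqrt(h^2 + p^2).
    """
    mtu_cm = mtu_len * 100.0
    h = muscle.height
    p = mtu_cm - muscle.tsl
    if p <= 0:
        if h == 0:
            raise DegenerateFibreError(
                f"{muscle.name}: MTU length {mtu_cm:.3f} cm does not exceed "
                f"tendon slack length {muscle.tsl:.3f} cm")
        # slack tendon: the fibre rests at its constant height and cannot
        # transmit force along the tendon line
        return FibreState(l_fibre=h, l_norm=h / muscle.l_opt,
                          cos_pennation=0.0)
    l_fibre = float(np.hypot(h, p))
    return FibreState(l_fibre=l_fibre, l_norm=l_fibre / muscle.l_opt,
                      cos_pennation=p / l_fibre)


def muscle_force(activation, muscle, fs):
    """Active tendon-direction force F = a * Fmax * f_L(l_norm) * cos(pennation) [N]."""
    a = np.asarray(activation, float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise InvalidParameterError(f"{muscle.name}: activation outside [0, 1]")
    return float(a) * muscle.fmax * active_force_length(fs.l_norm) * fs.cos_pennation


# ---------------------------------------------------------------------------
# kinematics of the chain
# ---------------------------------------------------------------------------


def _joint_rotation(model, joint_name, q, names):
    """Cardan rotation of a joint: flexion (Y), then ad/abduction (X'), then rotation (Z'')."""
    R = np.eye(3)
    for kind in DOF_KINDS:
        name = f"{joint_name}_{_KIND_SHORT[kind]}"
        if model.has_dof(name) and model.dof(name).enabled:
            d = model.dof(name)
            theta = q[names.index(name)]
            R = R @ Rotation.from_rotvec(d.axis * theta).as_matrix()
    return R


def forward_kinematics(model, posture):
    """World pose (R, p) of every segment for generalized coordinates q.

    Accepts a Posture or a bare coordinate vector; joint-range validation only
    happens when the Posture was constructed against the model.
    """
    q = posture.q if isinstance(posture, Posture) else np.asarray(posture, float)
    names = model.coordinate_names
    if len(q) != len(names):
        raise ModelConsistencyError(
            f"coordinate vector length {len(q)} != {len(names)}")
    R_pelvis = Rotation.from_euler("YXZ", [q[3], q[4], q[5]]).as_matrix()
    poses = {"pelvis": (R_pelvis, q[:3].copy())}
    for jname in JOINT_ORDER:
        joint = model.joints[jname]
        R_p, p_p = poses[joint.parent]
        p_c = p_p + R_p @ joint.location
        R_c = R_p @ _joint_rotation(model, jname, q, names)
        poses[joint.child] = (R_c, p_c)
    return poses


def mtu_length(model, posture, muscle):
    """Polyline length of the muscle path over the posed segments [m]."""
    poses = forward_kinematics(model, posture)
    pts = []
    for seg, local in muscle.path.via_points:
        if seg not in poses:
            raise ModelConsistencyError(
                f"muscle {muscle.name}: via point on unknown segment {seg!r}")
        R, p = poses[seg]
        pts.append(p + R @ local)
    pts = np.asarray(pts)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _all_mtu_lengths(model, posture):
    """MTU lengths for every model muscle at one posture (single FK evaluation)."""
    poses = forward_kinematics(model, posture)
    out = np.empty(len(model.muscles))
    for i, m in enumerate(model.muscles):
        pts = np.asarray([poses[s][1] + poses[s][0] @ loc
                          for s, loc in m.path.via_points])
        out[i] = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    return out


def moment_arm(model, posture, muscle, dof, step=1e-4):
    """Tendon-excursion moment arm r = -dL_mtu/dtheta [m] about one joint DOF.

    Central finite difference on the DOF coordinate.  Positive arm means the
    muscle produces a positive (extensor / abductor / external-rotator) moment.
    """
    name = dof if isinstance(dof, str) else dof.name
    d = model.dof(name)
    if not d.enabled:
        raise ModelConsistencyError(f"DOF {name} is disabled")
    if step <= 0 or step < 1e-12:
        raise InvalidParameterError("finite-difference step underflow")
    idx = model.coordinate_names.index(name)
    qp = posture.q.copy()
    qm = posture.q.copy()
    qp[idx] += step
    qm[idx] -= step
    # unvalidated Postures: perturbed coordinates may graze declared ranges
    lp = mtu_length(model, Posture(qp), muscle)
    lm = mtu_length(model, Posture(qm), muscle)
    return -(lp - lm) / (2 * step)


def moment_arm_matrix(model, posture, dofs=None, step=1e-4):
    """r[i, j] = moment arm of muscle i about enabled joint DOF j [m].

    Zero where a muscle does not span the DOF's joint.  Uses one FK pair per
    DOF (not per muscle) so trajectory solves stay cheap.
    """
    if dofs is None:
        dofs = model.enabled_joint_dofs
    n_m = len(model.muscles)
    R = np.zeros((n_m, len(dofs)))
    spans = [set(m.spanned_dofs) for m in model.muscles]
    for j, d in enumerate(dofs):
        idx = model.coordinate_names.index(d.name)
        qp = posture.q.copy(); qp[idx] += step
        qm = posture.q.copy(); qm[idx] -= step
        lp = _all_mtu_lengths(model, Posture(qp))
        lm = _all_mtu_lengths(model, Posture(qm))
        col = -(lp - lm) / (2 * step)
        for i in range(n_m):
            if d.name in spans[i]:
                R[i, j] = col[i]
    return R


# ---------------------------------------------------------------------------
# tendon slack length calibration
# ---------------------------------------------------------------------------


def tune_tsl_standing(muscle, standing_mtu_len, target=(0.8, 1.2),
                      tol=1e-6, max_iter=200):
    """Adjust tendon slack length so standing normalized fibre length is in target.

    If the muscle already lies inside [target] it is returned unchanged;
    otherwise TSL is moved (bisection, tolerance ``tol`` cm) until l_norm sits
    at the nearest target boundary.  Returns (tuned muscle, adjustment as a
    fraction of MTU length).
    """
    lo_t, hi_t = target
    if not (0 < lo_t <= hi_t):
        raise InvalidParameterError("target window must be within (0, inf)")
    mtu_cm = standing_mtu_len * 100.0

    def l_norm_at(tsl):
        m = replace(muscle, tsl=tsl)
        try:
            return fibre_state(standing_mtu_len, m).l_norm
        except DegenerateFibreError:
            return 0.0  # tendon slack: fibre carries no length

    ln = l_norm_at(muscle.tsl)
    if lo_t <= ln <= hi_t:
        return muscle, 0.0
    target_ln = hi_t if ln > hi_t else lo_t

    # l_norm decreases monotonically with tsl (p = mtu - tsl shrinks)
    lo, hi = 0.0, mtu_cm  # tsl bracket
    f_lo = l_norm_at(lo) - target_ln
    h = muscle.height
    f_hi = (h / muscle.l_opt if h > 0 else -np.inf)
    f_hi = f_hi - target_ln if np.isfinite(f_hi) else -np.inf
    if f_lo < 0:
        raise InfeasibleTuningError(
            f"{muscle.name}: no tsl >= 0 reaches l_norm {target_ln}")
    if f_hi >= 0:
        raise InfeasibleTuningError(
            f"{muscle.name}: pennation height prevents reaching l_norm {target_ln}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if l_norm_at(mid) - target_ln > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    new_tsl = 0.5 * (lo + hi)
    tuned = replace(muscle, tsl=new_tsl)
    return tuned, abs(new_tsl - muscle.tsl) / mtu_cm


def retune_fibre_range(muscle, mtu_len_series, bounds=(0.5, 1.5)):
    """Lengthen the optimal fibre (shortening TSL equally, conserving MTU rest
    length) until normalized fibre length stays within ``bounds`` over a motion.

    Returns (muscle', flagged) where flagged says whether a change was needed.
    """
    series = np.asarray(mtu_len_series, float)
    if series.size == 0:
        raise InvalidParameterError("empty MTU length series")
    lo_b, hi_b = bounds
    L = muscle.mtu_rest_length  # conserved, cm

    def ok(l_opt_new):
        tsl_new = L - l_opt_new
        if tsl_new < 0:
            return False
        m = replace(muscle, l_opt=l_opt_new, tsl=tsl_new)
        try:
            ln = np.array([fibre_state(x, m).l_norm for x in series])
        except DegenerateFibreError:
            return False  # tendon goes slack somewhere in the motion
        return np.all(ln >= lo_b - 1e-12) and np.all(ln <= hi_b + 1e-12)

    if ok(muscle.l_opt):
        return muscle, False
    # minimal feasible l_opt by bisection (feasibility is monotone in l_opt:
    # a longer fibre both widens the admissible band and re-centres it)
    lo, hi = muscle.l_opt, L
    if not ok(hi):
        raise InfeasibleTuningError(
            f"{muscle.name}: fibre cannot be kept within {bounds} even with "
            f"zero tendon slack length")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-9:
            break
    l_opt_new = hi
    tsl_new = L - l_opt_new
    if tsl_new < 0:
        raise InfeasibleTuningError(f"{muscle.name}: required tsl < 0")
    return replace(muscle, l_opt=l_opt_new, tsl=tsl_new), True


# ---------------------------------------------------------------------------
# subject scaling
# ---------------------------------------------------------------------------


def scale_model(model, subject_segment_lengths):
    """Scale the model to a subject from thigh/shank/foot lengths [m].

    Per-segment factor = subject length / model length; the pelvis factor is
    the arithmetic mean of the three limb factors.  Geometry scales linearly,
    masses by factor^3 and inertia by factor^5 (uniform density); each MTU rest
    length is rescaled by the mean factor of the segments its via points touch,
    preserving the l_opt : tsl ratio.
    """
    for seg in ("thigh", "shank", "foot"):
        if seg not in subject_segment_lengths:
            raise InvalidParameterError(f"missing subject length for {seg!r}")
        if subject_segment_lengths[seg] <= 0:
            raise InvalidParameterError(f"subject length for {seg!r} must be > 0")
    factors = {seg: subject_segment_lengths[seg] / model.segments[seg].length
               for seg in ("thigh", "shank", "foot")}
    factors["pelvis"] = float(np.mean([factors["thigh"], factors["shank"],
                                       factors["foot"]]))

    segments = {}
    for name, s in model.segments.items():
        f = factors[name]
        segments[name] = replace(
            s, mass=s.mass * f**3, com=s.com * f, inertia=s.inertia * f**5,
            length=s.length * f)
    joints = {name: replace(j, location=j.location * factors[j.parent])
              for name, j in model.joints.items()}
    markers = {name: (seg, np.asarray(loc) * factors[seg])
               for name, (seg, loc) in model.markers.items()}

    muscles = []
    for m in model.muscles:
        path = MusclePath(tuple((seg, np.asarray(loc) * factors[seg])
                                for seg, loc in m.path.via_points))
        f_mtu = float(np.mean([factors[seg] for seg in m.path.segments]))
        muscles.append(replace(m, path=path, l_opt=m.l_opt * f_mtu,
                               tsl=m.tsl * f_mtu))
    return replace(model, segments=segments, joints=joints, markers=markers,
                   muscles=tuple(muscles))


# ---------------------------------------------------------------------------
# packaged architecture table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["joint", "muscle", "abbreviation", "pcsa_cm2", "pennation_deg",
                  "fmax_N", "fibre_opt_measured_cm", "tsl_measured_cm",
                  "fibre_opt_model_cm", "tsl_model_cm"]


def load_muscle_table(path=None):
    """Load the greyhound hindlimb muscle-architecture table as a DataFrame.

    Columns: joint, muscle, abbreviation, pcsa_cm2, pennation_deg, fmax_N,
    fmax_lit_N (literature comparison, blank where unavailable), lit_group
    (muscles pooled in the literature value), fibre_opt_measured_cm,
    tsl_measured_cm, fibre_opt_model_cm, tsl_model_cm.  Printed fmax values
    are taken verbatim, not recomputed.
    """
    if path is None:
        path = importlib.resources.files("stsim.data") / "greyhound_hindlimb_muscles.csv"
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"muscle table missing columns: {missing}")
    return df


def muscle_table_ratios(df):
    """Measured / literature Fmax ratios, pooling muscles that the literature
    reports combined.  Returns a Series indexed by abbreviation (single
    muscles) or lit_group name (pooled entries)."""
    out = {}
    lone = df[df["fmax_lit_N"].notna() & df["lit_group"].isna()]
    for _, r in lone.iterrows():
        out[r["abbreviation"]] = r["fmax_N"] / r["fmax_lit_N"]
    for group, sub in df[df["lit_group"].notna()].groupby("lit_group"):
        lit = sub["fmax_lit_N"].dropna()
        if len(lit):
            out[group] = sub["fmax_N"].sum() / float(lit.iloc[0])
    return pd.Series(out)


def muscles_from_table(df, which="model"):
    """Build MuscleParams (without paths) from a table row set.

    ``which`` selects the 'measured' or 'model' fibre/TSL columns.  Fmax comes
    from the printed column.
    """
    if which not in ("measured", "model"):
        raise InvalidParameterError("which must be 'measured' or 'model'")
    out = []
    for _, r in df.iterrows():
        out.append(MuscleParams(
            name=r["abbreviation"], pcsa=r["pcsa_cm2"],
            pennation_opt=r["pennation_deg"], fmax=float(r["fmax_N"]),
            l_opt=r[f"fibre_opt_{which}_cm"], tsl=r[f"tsl_{which}_cm"]))
    return out
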