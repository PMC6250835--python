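"""Marker-based joint kinematics.

Marker clusters sampled at 180 Hz are gap-filled, low-pass filtered
(zero-phase 4th-order Butterworth, 6 Hz), turned into rigid segment poses by
orthogonal Procrustes against a static calibration, and decomposed into
Cardan Y-X'-Z'' joint angles (flexion/extension about Y).  Trial series are
screened against the group mean (~45 deg rule), time-normalized to a
100-point 0-100 %StS grid, and ensemble-averaged subject-first.

Angles are degrees at the API surface; increasing flexion/extension means
extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

MARKER_RATE = 180.0  # Hz

ANGLE_CHANNELS = ("flexion_extension", "ad_abduction", "int_ext_rotation")


class KinematicsError(ValueError):
    pass


class DegenerateFrameError(KinematicsError):
    pass


@dataclass
class MarkerTrajectory:
    """One marker's 3D position series [m]; NaN rows encode gaps."""

    name: str
    samples: np.ndarray  # (n, 3)
    rate: float = MARKER_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise KinematicsError(f"{self.name}: samples must be (n, 3)")

    @property
    def n_frames(self):
        return len(self.samples)

    def valid_mask(self):
        return ~np.any(np.isnan(self.samples), axis=1)


@dataclass
class SegmentPoseSeries:
    rotation: np.ndarray  # (n, 3, 3)
    translation: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)

    @property
    def n_frames(self):
        return len(self.rotation)


@dataclass
class JointAngleSeries:
    """Per-joint Cardan angle series in degrees.

    ``angles`` maps joint -> (n, 3) array with columns ordered as
    (flexion_extension, ad_abduction, int_ext_rotation).  ``grid`` is either a
    time vector [s] or a %StS vector after time normalization.
    """

    angles: dict
    grid: np.ndarray
    grid_is_percent: bool = False
    subject: str = ""
    sd: dict | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.angles = {j: np.atleast_2d(np.asarray(a, float))
                       for j, a in self.angles.items()}
        for j, a in self.angles.items():
            if a.shape != (len(self.grid), 3):
                raise KinematicsError(
                    f"{j}: angle block {a.shape} != ({len(self.grid)}, 3)")

    @property
    def n_frames(self):
        return len(self.grid)

    def channel(self, joint, channel):
        return self.angles[joint][:, ANGLE_CHANNELS.index(channel)]


@dataclass
class StaticCalibration:
    """Reference cluster geometry per segment, expressed in the anatomical
    (segment) frame, estimated from one standing trial."""

    reference: dict  # segment -> (marker names tuple, (k, 3) positions)


# ---------------------------------------------------------------------------
# filtering and gap handling
# ---------------------------------------------------------------------------


def fill_leading_gaps(traj, max_interior_gap=0.1):
    """Fill leading gaps with the first valid value; linearly interpolate
    interior gaps up to ``max_interior_gap`` seconds; flag longer ones.

    Returns (trajectory, flagged_gap_list) where each flag is a (start, stop)
    frame index pair left unfilled.
    """
    valid = traj.valid_mask()
    if not valid.any():
        raise KinematicsError(f"{traj.name}: all samples missing")
    out = traj.samples.copy()
    first = int(np.argmax(valid))
    out[:first] = out[first]
    valid = ~np.any(np.isnan(out), axis=1)
    flagged = []
    max_frames = int(round(max_interior_gap * traj.rate))
    idx = np.flatnonzero(valid)
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a > 1:
            gap = b - a - 1
            if gap <= max_frames:
                t = np.arange(1, gap + 1) / (b - a)
                out[a + 1:b] = out[a][None, :] * (1 - t[:, None]) + out[b][None, :] * t[:, None]
            else:
                flagged.append((int(a + 1), int(b)))
    if idx[-1] < len(out) - 1:  # trailing gap: hold last valid value
        out[idx[-1] + 1:] = out[idx[-1]]
    return replace(traj, samples=out), flagged


def lowpass_markers(traj, order=4, cutoff=6.0):
    """Zero-phase (forward-backward) Butterworth low-pass; DC gain exactly 1."""
    if not traj.valid_mask().all():
        raise KinematicsError(f"{traj.name}: fill gaps before filtering")
    if traj.n_frames < 20:
        raise KinematicsError(f"{traj.name}: too short to filter")
    b, a = butter(order, cutoff, fs=traj.rate)
    return replace(traj, samples=filtfilt(b, a, traj.samples, axis=0))


# ---------------------------------------------------------------------------
# rigid poses and Cardan angles
# ---------------------------------------------------------------------------


def _kabsch(ref, obs):
    """Least-squares rigid transform (R, t) with det(R) = +1 mapping ref -> obs."""
    cr = ref.mean(axis=0)
    co = obs.mean(axis=0)
    H = (ref - cr).T @ (obs - co)
    U, s, Vt = np.linalg.svd(H)
    # collinearity check: two near-zero singular values leave a rotation
    # about the cluster axis unconstrained
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-6:
        raise DegenerateFrameError("collinear or degenerate marker cluster")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = co - R @ cr
    return R, t


def segment_pose(cluster, calibration, segment):
    """Per-frame rigid pose of a segment from >=3 marker trajectories.

    ``cluster`` maps marker name -> MarkerTrajectory.  The calibration holds
    the same markers' positions in the segment's anatomical frame, so the
    Procrustes fit directly yields the anatomical pose.
    """
    names, ref = calibration.reference[segment]
    if len(names) < 3:
        raise KinematicsError(f"{segment}: need >= 3 markers")
    trajs = [cluster[n] for n in names]
    n = trajs[0].n_frames
    if any(t.n_frames != n for t in trajs):
        raise KinematicsError(f"{segment}: marker frame counts differ")
    Rs = np.empty((n, 3, 3))
    ts = np.empty((n, 3))
    for i in range(n):
        obs = np.array([t.samples[i] for t in trajs])
        if np.any(np.isnan(obs)):
            raise KinematicsError(
                f"{segment}: gap at frame {i}; fill gaps first")
        Rs[i], ts[i] = _kabsch(np.asarray(ref, float), obs)
    return SegmentPoseSeries(rotation=Rs, translation=ts)


def cardan_yxz(R_rel, gimbal_tol=1e-6):
    """Cardan Y-X'-Z'' decomposition, degrees.  R = Ry(ty) Rx(tx) Rz(tz).

    Returns (ty, tx, tz, gimbal_flag).  Near gimbal lock (|cos tx| < tol) the
    third angle is zeroed and the frame flagged.
    """
    R_rel = np.asarray(R_rel, float)
    if np.max(np.abs(R_rel @ R_rel.T - np.eye(3))) > 1e-6:
        raise KinematicsError("input is not orthogonal within tolerance")
    sx = -R_rel[1, 2]
    sx = np.clip(sx, -1.0, 1.0)
    tx = np.arcsin(sx)
    if abs(np.cos(tx)) < gimbal_tol:
        # Y and Z rotations degenerate; attribute everything to ty
        ty = np.arctan2(R_rel[0, 1] * np.sign(sx), R_rel[0, 0])
        return (np.rad2deg(ty), np.rad2deg(tx), 0.0, True)
    ty = np.arctan2(R_rel[0, 2], R_rel[2, 2])
    tz = np.arctan2(R_rel[1, 0], R_rel[1, 1])
    return (np.rad2deg(ty), np.rad2deg(tx), np.rad2deg(tz), False)


def compose_cardan_yxz(ty, tx, tz, degrees=True):
    """Inverse of cardan_yxz: build the rotation matrix."""
    return Rotation.from_euler("YXZ", [ty, tx, tz], degrees=degrees).as_matrix()


def joint_angles(parent, child, sign_map=None, joint="joint", rate=MARKER_RATE):
    """Cardan joint angles of child relative to parent, extension-positive.

    ``sign_map`` maps channel name -> +-1 remapping raw Cardan angles onto the
    convention that extension, abduction and external rotation increase.
    Angles are unwrapped so no inter-frame jump exceeds 180 deg.
    """
    if parent.n_frames != child.n_frames:
        raise KinematicsError("parent/child frame counts differ")
    signs = np.array([(sign_map or {}).get(c, 1.0) for c in ANGLE_CHANNELS])
    n = parent.n_frames
    raw = np.empty((n, 3))
    for i in range(n):
        R_rel = parent.rotation[i].T @ child.rotation[i]
        ty, tx, tz, _ = cardan_yxz(R_rel)
        raw[i] = (ty, tx, tz)
    raw = np.rad2deg(np.unwrap(np.deg2rad(raw), axis=0))
    t = np.arange(n) / rate
    return JointAngleSeries(angles={joint: raw * signs}, grid=t)


def merge_joint_series(series_list):
    """Combine per-joint JointAngleSeries sharing one grid into a single series."""
    base = series_list[0]
    angles = {}
    for s in series_list:
        if s.n_frames != base.n_frames:
            raise KinematicsError("grid mismatch while merging")
        angles.update(s.angles)
    return JointAngleSeries(angles=angles, grid=base.grid,
                            grid_is_percent=base.grid_is_percent,
                            subject=base.subject)


# ---------------------------------------------------------------------------
# trial screening, normalization, averaging
# ---------------------------------------------------------------------------


def exclude_outlier_trials(trials, group_mean, threshold=45.0, mode="max"):
    """Drop trials deviating from the group mean by more than ``threshold`` deg.

    ``mode`` 'max' uses the peak absolute deviation over the cycle (default);
    'mean' uses the cycle-average deviation.  Returns (retained, report) where
    the report lists (trial index, joint, channel, peak deviation).
    """
    if not trials:
        raise KinematicsError("no trials given")
    retained, report = [], []
    for k, tr in enumerate(trials):
        worst = None
        for j, block in tr.angles.items():
            dev = np.abs(block - group_mean.angles[j])
            stat = dev.max(axis=0) if mode == "max" else dev.mean(axis=0)
            c = int(np.argmax(stat))
            if worst is None or stat[c] > worst[3]:
                worst = (k, j, ANGLE_CHANNELS[c], float(stat[c]))
        if worst[3] > threshold:
            report.append(worst)
        else:
            retained.append(tr)
    return retained, report


def time_normalize(series, n_points=100, start=None, end=None):
    """Resample onto a uniform 0-100 %StS grid (inclusive endpoints) by linear
    interpolation.  ``start``/``end`` select the StS event window on the
    original grid; defaults span the whole series."""
    if series.n_frames < 2:
        raise KinematicsError("need >= 2 frames")
    t0 = series.grid[0] if start is None else float(start)
    t1 = series.grid[-1] if end is None else float(end)
    if t1 <= t0:
        raise KinematicsError("end must exceed start")
    tq = np.linspace(t0, t1, n_points)
    angles = {j: np.column_stack([np.interp(tq, series.grid, block[:, c])
                                  for c in range(3)])
              for j, block in series.angles.items()}
    pct = np.linspace(0.0, 100.0, n_points)
    return JointAngleSeries(angles=angles, grid=pct, grid_is_percent=True,
                            subject=series.subject)


def detect_sts_events(series, vel_threshold=5.0, sustain=0.05,
                      settle_tol=2.0, rate=MARKER_RATE):
    """Heuristic StS start/end events on a time-based joint-angle series.

    Start: first frame where any joint's extension velocity exceeds
    ``vel_threshold`` deg/s sustained for ``sustain`` seconds.  End: first
    frame after which every angle stays within ``settle_tol`` deg of its final
    value.  Returns (t_start, t_end).
    """
    fe = np.column_stack([series.channel(j, "flexion_extension")
                          for j in series.angles])
    vel = np.gradient(fe, series.grid, axis=0)
    fast = np.any(vel > vel_threshold, axis=1)
    need = max(1, int(round(sustain * rate)))
    start_idx = 0
    run = 0
    for i, f in enumerate(fast):
        run = run + 1 if f else 0
        if run >= need:
            start_idx = i - need + 1
            break
    final = fe[-1]
    settled = np.all(np.abs(fe - final) <= settle_tol, axis=1)
    end_idx = len(fe) - 1
    for i in range(len(fe) - 1, -1, -1):
        if not settled[i]:
            end_idx = min(i + 1, len(fe) - 1)
            break
    return float(series.grid[start_idx]), float(series.grid[end_idx])


def ensemble_average(trials_by_subject):
    """Subject-first ensemble mean and between-subject SD on the %StS grid."""
    subject_means = []
    for subject, trials in trials_by_subject.items():
        if not trials:
            raise KinematicsError(f"subject {subject!r} has no trials")
        joints = trials[0].angles.keys()
        mean = {j: np.mean([t.angles[j] for t in trials], axis=0)
                for j in joints}
        subject_means.append(mean)
    joints = subject_means[0].keys()
    grand = {j: np.mean([m[j] for m in subject_means], axis=0) for j in joints}
    if len(subject_means) > 1:
        sd = {j: np.std([m[j] for m in subject_means], axis=0, ddof=1)
              for j in joints}
    else:
        sd = {j: np.zeros_like(grand[j]) for j in joints}
    ref = next(iter(trials_by_subject.values()))[0]
    return JointAngleSeries(angles=grand, grid=ref.grid,
                            grid_is_percent=ref.grid_is_percent, sd=sd)


def range_of_motion(series):
    """max - min over the cycle, per joint and channel [deg]."""
    return {j: block.max(axis=0) - block.min(axis=0)
            for j, block in series.angles.items()}
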