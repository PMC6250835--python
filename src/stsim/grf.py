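"""Force-plate processing into a single-hindlimb ground-reaction wrench.

Raw plate records (1,800 Hz) are de-meaned against an unloaded baseline
window, zero-phase low-pass filtered (4th-order Butterworth, 6 Hz), and
decimated to the 180 Hz marker clock.  Both hindfeet share one plate, so the
single-limb wrench halves the vertical and craniocaudal components and zeroes
the mediolateral one; the centre of pressure is constrained to the foot
midline.  Components are ordered (craniocaudal X, mediolateral Y, vertical Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

PLATE_RATE = 1800.0
TARGET_RATE = 180.0
COP_FORCE_THRESHOLD = 5.0  # N vertical force below which the CoP is undefined


class GrfError(ValueError):
    pass


@dataclass
class ForcePlateRecord:
    force: np.ndarray  # (n, 3) N
    cop: np.ndarray | None = None  # (n, 3) m, plate frame
    plate: str = "hindlimb"
    rate: float = PLATE_RATE
    both_feet_on_plate: bool = True

    def __post_init__(self):
        self.force = np.asarray(self.force, float)
        if self.cop is not None:
            self.cop = np.asarray(self.cop, float)
        if not np.all(np.isfinite(self.force)):
            raise GrfError("non-finite force samples")

    @property
    def n_samples(self):
        return len(self.force)


@dataclass
class LimbWrench:
    """Single-limb GRF series at the marker rate."""

    grf: np.ndarray  # (n, 3) N
    cop: np.ndarray | None = None  # (n, 3) m
    cop_defined: np.ndarray | None = None  # (n,) bool
    rate: float = TARGET_RATE
    bw_normalized: np.ndarray | None = None

    def __post_init__(self):
        self.grf = np.asarray(self.grf, float)
        if self.cop is not None:
            self.cop = np.asarray(self.cop, float)

    @property
    def n_samples(self):
        return len(self.grf)


def preprocess_grf(raw, baseline_window=0.2, cutoff=6.0, order=4,
                   target_rate=TARGET_RATE):
    """De-mean, zero-phase low-pass filter and decimate a plate record.

    The per-channel baseline is the mean over the first ``baseline_window``
    seconds (an unloaded interval); decimation keeps every
    rate/target_rate-th sample after filtering.
    """
    n_base = int(round(baseline_window * raw.rate))
    if n_base < 1 or n_base > raw.n_samples:
        raise GrfError("baseline window outside the record")
    step = raw.rate / target_rate
    if abs(step - round(step)) > 1e-9:
        raise GrfError("plate rate must be an integer multiple of target rate")
    step = int(round(step))
    force = raw.force - raw.force[:n_base].mean(axis=0)
    b, a = butter(order, cutoff, fs=raw.rate)
    force = filtfilt(b, a, force, axis=0)[::step]
    cop = None
    if raw.cop is not None:
        cop = raw.cop[::step]
    return replace(raw, force=force, cop=cop, rate=target_rate)


def split_bilateral(hind_plate):
    """Single-limb wrench from the combined bilateral hindlimb plate.

    Vertical and craniocaudal components are halved (bilateral symmetry);
    the mediolateral component is set to zero.
    """
    if not hind_plate.both_feet_on_plate:
        raise GrfError("trial invalid: both hindfeet must stay on the plate")
    grf = hind_plate.force.copy() / 2.0
    grf[:, 1] = 0.0
    return LimbWrench(grf=grf, cop=None, rate=hind_plate.rate)


def compose_cop(wrench, plate_cop_x, foot_ankle, foot_mth, plate_z=0.0,
                force_threshold=COP_FORCE_THRESHOLD):
    """Composite CoP: craniocaudal coordinate from the plate, mediolateral
    coordinate projected onto the foot midline, vertical at the plate surface.

    ``foot_ankle`` and ``foot_mth`` are (n, 3) marker series defining the foot
    midline (lateral malleolus to metatarsal head, or midpoints of the
    lateral/medial pairs when present).  Frames with vertical force below
    ``force_threshold`` are flagged undefined.
    """
    plate_cop_x = np.asarray(plate_cop_x, float)
    a = np.asarray(foot_ankle, float)
    b = np.asarray(foot_mth, float)
    n = wrench.n_samples
    if len(plate_cop_x) != n or len(a) != n or len(b) != n:
        raise GrfError("CoP/marker series length mismatch")
    axis = b[:, :2] - a[:, :2]
    seg = np.linalg.norm(axis, axis=1)
    if np.any(seg < 0.01):
        raise GrfError("degenerate foot midline (< 1 cm marker separation)")
    # param t along the midline whose craniocaudal (x) coordinate matches the plate
    dx = axis[:, 0]
    dx = np.where(np.abs(dx) < 1e-9, 1e-9, dx)
    t = (plate_cop_x - a[:, 0]) / dx
    cop = np.column_stack([
        plate_cop_x,
        a[:, 1] + t * axis[:, 1],
        np.full(n, plate_z),
    ])
    defined = wrench.grf[:, 2] >= force_threshold
    cop[~defined] = np.nan
    return replace(wrench, cop=cop, cop_defined=defined), t


def normalize_forces(wrench, body_mass, g=9.81):
    """Dimensionless copy of the wrench in body-weight units."""
    if body_mass <= 0:
        raise GrfError("body mass must be > 0")
    bw = wrench.grf / (body_mass * g)
    return replace(wrench, bw_normalized=bw)
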