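"""Text formats: TRC marker files, STO/MOT time-series files, YAML run config.

All files are tab-delimited with period decimal separators and UNIX newlines.
TRC units may be mm or m (header-honoured, metres internally).  STO headers
end with ``endheader``; the first column is time and must increase strictly.
The resolved run configuration is embedded in output headers for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .kinematics import MarkerTrajectory


class FileFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved processing constants (filter orders/cutoffs, thresholds,
    normalization inputs) with the analysis defaults."""

    marker_filter_order: int = 4
    marker_filter_cutoff_hz: float = 6.0
    grf_filter_order: int = 4
    grf_filter_cutoff_hz: float = 6.0
    id_filter_order: int = 3
    id_filter_cutoff_hz: float = 6.0
    marker_rate_hz: float = 180.0
    plate_rate_hz: float = 1800.0
    outlier_threshold_deg: float = 45.0
    report_activation_threshold: float = 0.2
    report_force_threshold_bw: float = 0.2
    reserve_limit_nm: float = 1.0
    reserve_limit_pct: float = 5.0
    reserve_scale_nm: float = 1.0
    body_mass_kg: float = 27.0
    leg_length_m: float = 0.616
    gravity: float = 9.81
    seed: int = 0

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def header_lines(self):
        return [f"config.{k}={v}" for k, v in sorted(asdict(self).items())]


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------


def write_trc(path, markers, rate=180.0, units="m"):
    """Write a marker dictionary to TRC.  Missing samples become blank cells."""
    names = list(markers)
    n = markers[names[0]].n_frames
    scale = 1000.0 if units == "mm" else 1.0
    import os
    with open(path, "w", newline="\n") as f:
        f.write(f"PathFileType\t4\t(X/Y/Z)\t{os.path.basename(str(path))}\n")
        f.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        f.write(f"{rate:.2f}\t{rate:.2f}\t{n}\t{len(names)}\t{units}\t"
                f"{rate:.2f}\t1\t{n}\n")
        f.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        f.write("\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))) + "\n")
        f.write("\n")
        for i in range(n):
            row = [str(i + 1), f"{i / rate:.6f}"]
            for name in names:
                p = markers[name].samples[i]
                if np.any(np.isnan(p)):
                    row += ["", "", ""]
                else:
                    row += [f"{v * scale:.8f}" for v in p]
            f.write("\t".join(row) + "\n")


def read_trc(path):
    """Read a TRC file into a marker dictionary (metres internally)."""
    with open(path) as f:
        lines = f.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FileFormatError(f"{path}: not a TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        rate = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"]
    except (KeyError, ValueError) as e:
        raise FileFormatError(f"{path}: malformed TRC header ({e})")
    names = [s for s in lines[3].split("\t")[2:] if s]
    if len(names) != n_markers:
        raise FileFormatError(
            f"{path}: NumMarkers={n_markers} but {len(names)} marker names")
    scale = 0.001 if units.lower() == "mm" else 1.0
    data = {name: np.full((n_frames, 3), np.nan) for name in names}
    row_i = 0
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        expect = 2 + 3 * n_markers
        if len(cells) < expect:
            cells = cells + [""] * (expect - len(cells))
        elif len(cells) > expect:
            raise FileFormatError(f"{path}:{lineno}: too many columns")
        for k, name in enumerate(names):
            trip = cells[2 + 3 * k: 5 + 3 * k]
            if all(c.strip() for c in trip):
                data[name][row_i] = [float(c) * scale for c in trip]
        row_i += 1
        if row_i == n_frames:
            break
    if row_i != n_frames:
        raise FileFormatError(
            f"{path}: NumFrames={n_frames} but only {row_i} data rows")
    return {name: MarkerTrajectory(name, xyz, rate=rate)
            for name, xyz in data.items()}


# ---------------------------------------------------------------------------
# STO / MOT
# ---------------------------------------------------------------------------


def write_sto(path, time, columns, name="stsim", in_degrees=None,
              extra_header=()):
    """Write a labelled time series; ``columns`` maps label -> 1-D array."""
    time = np.asarray(time, float)
    labels = list(columns)
    with open(path, "w", newline="\n") as f:
        f.write(f"{name}\n")
        f.write(f"version=1\nnRows={len(time)}\nnColumns={1 + len(labels)}\n")
        if in_degrees is not None:
            f.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        for line in extra_header:
            f.write(line + "\n")
        f.write("endheader\n")
        f.write("time\t" + "\t".join(labels) + "\n")
        cols = [np.asarray(columns[k], float) for k in labels]
        for i, t in enumerate(time):
            f.write(f"{t:.8f}\t" + "\t".join(f"{c[i]:.8f}" for c in cols) + "\n")


def read_sto(path):
    """Read an STO/MOT file -> (time, {label: array}, header lines)."""
    with open(path) as f:
        lines = f.read().splitlines()
    header = []
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            break
        header.append(line)
    else:
        raise FileFormatError(f"{path}: missing endheader")
    labels = lines[i + 1].split("\t")
    if not labels or labels[0] != "time":
        raise FileFormatError(f"{path}: first column must be 'time'")
    rows = [list(map(float, ln.split("\t")))
            for ln in lines[i + 2:] if ln.strip()]
    data = np.asarray(rows, float)
    if data.size == 0:
        raise FileFormatError(f"{path}: no data rows")
    time = data[:, 0]
    if np.any(np.diff(time) <= 0):
        raise FileFormatError(f"{path}: time must increase strictly")
    return time, {lab: data[:, k + 1] for k, lab in enumerate(labels[1:])}, header


def write_external_loads(path, time, wrench, name="ground_reaction"):
    """MOT external-loads writer (ground_force_v*/p* columns)."""
    cop = wrench.cop if wrench.cop is not None else np.zeros_like(wrench.grf)
    cop = np.where(np.isnan(cop), 0.0, cop)
    cols = {
        "ground_force_vx": wrench.grf[:, 0],
        "ground_force_vy": wrench.grf[:, 1],
        "ground_force_vz": wrench.grf[:, 2],
        "ground_force_px": cop[:, 0],
        "ground_force_py": cop[:, 1],
        "ground_force_pz": cop[:, 2],
    }
    write_sto(path, time, cols, name=name, in_degrees=False)


def read_force_table(path):
    """Tab-delimited plate record: time, Fx, Fy, Fz [, COPx, COPy [, Mz]]."""
    rows = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and not _is_float(cells[0]):
                continue  # header row
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise FileFormatError(f"{path}:{lineno}: non-numeric cell")
    data = np.asarray(rows, float)
    if data.ndim != 2 or data.shape[1] < 4:
        raise FileFormatError(f"{path}: need at least time, Fx, Fy, Fz")
    time = data[:, 0]
    force = data[:, 1:4]
    cop = None
    if data.shape[1] >= 6:
        cop = np.column_stack([data[:, 4], data[:, 5], np.zeros(len(data))])
    return time, force, cop


def _is_float(s):
    try:
        float(s)
        return True
    except ValueError:
        return False
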