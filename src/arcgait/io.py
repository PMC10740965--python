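"""Readers and writers: TRC marker files, steps/angles CSV, report JSON.

Internal units are meters and seconds; TRC files declaring millimeters
are converted on read.  CSV schemas (documented per function) round-trip
all numeric fields losslessly and preserve unknown extra columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .events import DEFAULT_AXES, MarkerTrajectory, StepRecord
from .features import JointAngleSeries

__all__ = [
    "read_trc",
    "write_trc",
    "read_steps_csv",
    "write_steps_csv",
    "steps_to_frame",
    "frame_to_steps",
    "read_angles_csv",
    "write_angles_csv",
    "write_report_json",
]

STEP_COLUMNS = ["side", "t_strike", "stride_m", "step_m", "duration_s", "rho", "label"]
ANGLE_COLUMNS = ["t", "hip", "knee", "ankle", "side"]

_UNIT_SCALE = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}


def read_trc(path, axes: dict | None = None) -> dict:
    """Read a TRC marker file into ``{label: MarkerTrajectory}``.

    The header's declared units are converted to meters and the data rate
    is cross-checked against the time column.  ``axes`` maps
    forward/lateral/vertical onto the X/Y/Z columns (default X forward,
    Z vertical).  Malformed headers or rows raise :class:`ParseError`
    naming the offending line.
    """
    if axes is None:
        axes = dict(DEFAULT_AXES)
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC file ({len(lines)} lines, need >= 6)")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: line 2-3: malformed TRC header ({exc})") from exc
    if units not in _UNIT_SCALE:
        raise ParseError(f"{path}: line 3: unknown units {units!r}")
    scale = _UNIT_SCALE[units]
    marker_row = lines[3].split("\t")
    labels = [c.strip() for c in marker_row[2:] if c.strip()]
    if len(labels) != n_markers:
        raise ParseError(
            f"{path}: line 4: {len(labels)} marker labels but header says {n_markers}"
        )
    n_cols = 2 + 3 * n_markers
    t = np.empty(n_frames)
    pos = np.empty((n_frames, 3 * n_markers))
    row = 0
    for ln, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < n_cols:
            raise ParseError(f"{path}: line {ln}: expected {n_cols} columns, got {len(fields)}")
        if row >= n_frames:
            raise ParseError(f"{path}: line {ln}: more data rows than NumFrames={n_frames}")
        try:
            t[row] = float(fields[1])
            pos[row] = [float(v) for v in fields[2:n_cols]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-numeric value ({exc})") from exc
        row += 1
    if row != n_frames:
        raise ParseError(f"{path}: {row} data rows found but NumFrames={n_frames}")
    if n_frames >= 2 and abs(1.0 / (t[1] - t[0]) - rate) > 0.5:
        raise ParseError(f"{path}: time column rate disagrees with DataRate={rate}")
    out = {}
    for k, label in enumerate(labels):
        out[label] = MarkerTrajectory(
            t=t.copy(), pos=pos[:, 3 * k : 3 * k + 3] * scale, label=label, axes=dict(axes)
        )
    return out


def write_trc(trajectories: dict, path, units: str = "mm") -> None:
    """Write ``{label: MarkerTrajectory}`` to a TRC file (shared grid)."""
    trajs = list(trajectories.values())
    if not trajs:
        raise SchemaError("no trajectories to write")
    t = trajs[0].t
    rate = trajs[0].rate
    scale = 1.0 / _UNIT_SCALE[units]
    labels = list(trajectories)
    name = Path(path).name
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:.1f}\t{rate:.1f}\t{t.size}\t{len(labels)}\t{units}\t{rate:.1f}\t1\t{t.size}",
        "Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t",
        "\t\t" + "\t".join(f"X{k + 1}\tY{k + 1}\tZ{k + 1}" for k in range(len(labels))),
    ]
    for i in range(t.size):
        vals = []
        for lb in labels:
            vals.extend(f"{v * scale:.6f}" for v in trajectories[lb].pos[i])
        lines.append(f"{i + 1}\t{t[i]:.5f}\t" + "\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def steps_to_frame(records: list) -> pd.DataFrame:
    """Step records -> DataFrame with the documented steps schema."""
    return pd.DataFrame(
        [
            {
                "side": r.side,
                "t_strike": r.t_strike,
                "stride_m": r.stride_length,
                "step_m": r.step_length,
                "duration_s": r.duration,
                "rho": r.rho,
                "label": r.label if r.label is not None else "",
                "singular": r.singular,
            }
            for r in records
        ]
    )


def frame_to_steps(df: pd.DataFrame) -> list:
    """DataFrame (steps schema) -> list of StepRecord."""
    records = []
    for _, row in df.iterrows():
        label = row.get("label", "")
        records.append(
            StepRecord(
                stride_length=float(row["stride_m"]),
                step_length=float(row["step_m"]),
                duration=float(row["duration_s"]),
                rho=float(row["rho"]),
                side=str(row["side"]),
                label=None if (pd.isna(label) or label == "") else str(label),
                singular=bool(row.get("singular", False)),
                t_strike=float(row["t_strike"]),
            )
        )
    return records


def _check_columns(df: pd.DataFrame, required: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_steps_csv(path) -> pd.DataFrame:
    """Read a steps CSV (schema: side, t_strike, stride_m, step_m,
    duration_s, rho, label; extra columns preserved).  An empty file
    yields an empty frame with the schema columns."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=STEP_COLUMNS)
    if df.empty and df.columns.size == 0:
        return pd.DataFrame(columns=STEP_COLUMNS)
    _check_columns(df, STEP_COLUMNS, path)
    return df


def write_steps_csv(records_or_frame, path) -> None:
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else steps_to_frame(records_or_frame)
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_angles_csv(path) -> JointAngleSeries:
    """Read a joint-angle CSV (schema: t, hip, knee, ankle, side)."""
    df = pd.read_csv(path)
    _check_columns(df, ANGLE_COLUMNS, path)
    side = str(df["side"].iloc[0]) if len(df) else "left"
    return JointAngleSeries(
        t=df["t"].to_numpy(float),
        hip=df["hip"].to_numpy(float),
        knee=df["knee"].to_numpy(float),
        ankle=df["ankle"].to_numpy(float),
        side=side,
    )


def write_angles_csv(series: JointAngleSeries, path) -> None:
    pd.DataFrame(
        {
            "t": series.t,
            "hip": series.hip,
            "knee": series.knee,
            "ankle": series.ankle,
            "side": series.side,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def write_report_json(report: dict, path) -> None:
    """Write an analysis report (JSON, numpy types coerced)."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
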