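"""Readers and writers for the motion-capture interchange dialects.

TRC files carry labeled 3-D point trajectories (tab-separated X/Y/Z triplets
with a DataRate/NumFrames/NumMarkers header, units mm or m); STO/MOT files
carry named time series (nRows/nColumns header, ``endheader`` sentinel, time
column first).  Both round-trip losslessly including missing samples, which
are written as empty fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .preprocess import ScaleSet
from .trajectories import CAMERA_LABELS, PoseTrajectory, TrajectorySet

__all__ = [
    "ParseError",
    "read_trc",
    "write_trc",
    "read_sto",
    "write_sto",
    "write_pose_sto",
    "read_pose_sto",
    "write_scales",
    "read_scales",
]


class ParseError(ValueError):
    """Malformed interchange file; the message names the offending line."""


# ---------------------------------------------------------------------------
# TRC


def write_trc(ts: TrajectorySet, path, units: str = "m") -> None:
    path = Path(path)
    if units not in ("m", "mm"):
        raise ValueError("units must be 'm' or 'mm'")
    scale = 1000.0 if units == "mm" else 1.0
    n = ts.n_frames
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{ts.rate:g}\t{ts.rate:g}\t{n}\t{len(ts.labels)}\t{units}\t"
            f"{ts.rate:g}\t1\t{n}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(ts.labels) + "\t\t\n")
        comps = "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(ts.labels))
        )
        fh.write(f"\t\t{comps}\n\n")
        for i in range(n):
            fields = [str(i + 1), f"{ts.times[i]:.10f}"]
            for lab in ts.labels:
                p = ts.points[lab][i]
                if np.any(np.isnan(p)):
                    fields.extend(["", "", ""])
                else:
                    fields.extend(f"{v * scale:.8f}" for v in p)
            fh.write("\t".join(fields) + "\n")


def _infer_stream_kind(labels) -> str:
    if any(lab in ("Mid spine", "Mid thorax") for lab in labels):
        return "camera"
    if set(labels) <= set(CAMERA_LABELS):
        return "camera"
    return "marker"


def read_trc(path, stream_kind: Optional[str] = None, meta: Optional[dict] = None) -> TrajectorySet:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated header (only {len(lines)} lines)")
    if not lines[0].startswith("PathFileType"):
        raise ParseError(f"{path}:1: expected PathFileType header")
    hdr = lines[2].split("\t")
    if len(hdr) < 5:
        raise ParseError(f"{path}:3: incomplete header values")
    try:
        rate = float(hdr[0])
        n_frames = int(hdr[2])
        n_markers = int(hdr[3])
    except ValueError as exc:
        raise ParseError(f"{path}:3: bad header value ({exc})") from None
    units = hdr[4].strip()
    if units not in ("m", "mm"):
        raise ParseError(f"{path}:3: unsupported units {units!r} (need m or mm)")
    scale = 0.001 if units == "mm" else 1.0
    label_fields = lines[3].split("\t")
    if label_fields[0] != "Frame#":
        raise ParseError(f"{path}:4: expected marker label row starting with Frame#")
    labels = [f for f in label_fields[2:] if f.strip()]
    if len(labels) != n_markers:
        raise ParseError(
            f"{path}:4: header declares {n_markers} markers but found {len(labels)} labels"
        )
    data_start = 5
    while data_start < len(lines) and not lines[data_start].strip():
        data_start += 1
    times = np.empty(n_frames)
    points = {lab: np.empty((n_frames, 3)) for lab in labels}
    row = 0
    for ln in range(data_start, len(lines)):
        raw = lines[ln]
        if not raw.strip():
            continue
        if row >= n_frames:
            raise ParseError(f"{path}:{ln + 1}: more data rows than NumFrames")
        fields = raw.split("\t")
        if len(fields) < 2 + 3 * len(labels):
            fields = fields + [""] * (2 + 3 * len(labels) - len(fields))
        try:
            times[row] = float(fields[1])
            for j, lab in enumerate(labels):
                trip = fields[2 + 3 * j : 5 + 3 * j]
                if any(not f.strip() for f in trip):
                    points[lab][row] = np.nan
                else:
                    points[lab][row] = [float(f) * scale for f in trip]
        except ValueError as exc:
            raise ParseError(f"{path}:{ln + 1}: bad data value ({exc})") from None
        row += 1
    if row != n_frames:
        raise ParseError(
            f"{path}: header declares {n_frames} frames but file has {row} data rows"
        )
    kind = stream_kind or _infer_stream_kind(labels)
    return TrajectorySet(
        labels=labels,
        times=times,
        points=points,
        rate=rate,
        stream_kind=kind,
        meta=meta or {"source": str(path)},
    )


# ---------------------------------------------------------------------------
# STO / MOT


def write_sto(
    times: np.ndarray,
    columns: Dict[str, np.ndarray],
    path,
    name: str = "series",
    in_degrees: bool = True,
) -> None:
    path = Path(path)
    times = np.asarray(times, dtype=float)
    n = len(times)
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={n}\nnColumns={len(columns) + 1}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\nendheader\n")
        fh.write("time\t" + "\t".join(columns) + "\n")
        cols = [np.asarray(v, dtype=float) for v in columns.values()]
        for i in range(n):
            fh.write(
                f"{times[i]:.10f}\t" + "\t".join(f"{c[i]:.8f}" for c in cols) + "\n"
            )


def read_sto(path) -> Tuple[np.ndarray, Dict[str, np.ndarray], dict]:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = {}
    header_end = None
    for i, raw in enumerate(lines):
        if raw.strip() == "endheader":
            header_end = i
            break
        if "=" in raw:
            key, _, val = raw.partition("=")
            meta[key.strip()] = val.strip()
        elif i == 0:
            meta["name"] = raw.strip()
    if header_end is None:
        raise ParseError(f"{path}: missing endheader")
    if header_end + 1 >= len(lines):
        raise ParseError(f"{path}: missing column header row")
    cols = lines[header_end + 1].split("\t")
    if not cols or cols[0] != "time":
        raise ParseError(f"{path}:{header_end + 2}: first column must be 'time'")
    names = cols[1:]
    rows = []
    for ln in range(header_end + 2, len(lines)):
        raw = lines[ln]
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(cols):
            raise ParseError(
                f"{path}:{ln + 1}: expected {len(cols)} fields, got {len(fields)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln + 1}: bad value ({exc})") from None
    data = np.asarray(rows)
    if len(data) == 0:
        raise ParseError(f"{path}: no data rows")
    times = data[:, 0]
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: time column is not strictly increasing")
    return times, {n: data[:, j + 1] for j, n in enumerate(names)}, meta


def write_pose_sto(pose: PoseTrajectory, path, name: str = "coordinates") -> None:
    write_sto(pose.times, pose.coordinates, path, name=name, in_degrees=True)


def read_pose_sto(path) -> PoseTrajectory:
    times, columns, meta = read_sto(path)
    return PoseTrajectory(times=times, coordinates=columns, meta=meta)


# ---------------------------------------------------------------------------
# scale sets


def write_scales(scales: ScaleSet, path) -> None:
    data = {
        "method": scales.method,
        "static_pose_source": scales.static_pose_source,
        "factors": {seg: [float(v) for v in f] for seg, f in scales.factors.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_scales(path) -> ScaleSet:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScaleSet(
        factors={seg: np.asarray(f, dtype=float) for seg, f in data["factors"].items()},
        method=data.get("method", "uniform"),
        static_pose_source=data.get("static_pose_source", ""),
    )
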