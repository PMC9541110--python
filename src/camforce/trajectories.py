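"""Shared time-series containers for measurement streams and joint-coordinate data.

Two container types flow through the whole pipeline:

* :class:`TrajectorySet` — labeled 3-D point trajectories, either a 400 Hz
  marker stream (reflective landmarks) or a 30 Hz camera stream (pose-estimated
  joint centers).  Missing samples are NaN.
* :class:`PoseTrajectory` — generalized-coordinate time series on the kinematic
  chain, in degrees at every interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

#: Landmark labels of the marker-based stream (12 reflective markers).
MARKER_LABELS: tuple = (
    "Incisura Jugularis",
    "Processus Xiphoideus",
    "Cervical Vertebrae 7",
    "Thoracic Vertebrae 10",
    "Acromion",
    "Epicondylus Medialis",
    "Epicondylus Lateralis",
    "Upper arm",
    "Head of the Ulna",
    "Styloid processes of radius",
    "Lower arm",
    "Interphalangealis proximal III",
)

#: Joint-center labels of the single-camera stream (5 of the 17 pose keypoints).
CAMERA_LABELS: tuple = (
    "Mid spine",
    "Mid thorax",
    "Shoulder joint center",
    "Elbow joint center",
    "Wrist joint center",
)

#: Joint-center labels that preprocessing may append to a marker stream.
CENTER_LABELS: tuple = (
    "Shoulder joint center",
    "Elbow joint center",
    "Wrist joint center",
)

_ALLOWED = {
    "marker": set(MARKER_LABELS) | set(CENTER_LABELS),
    "camera": set(CAMERA_LABELS),
}


@dataclass
class TrajectorySet:
    """Labeled 3-D point time series with a uniform sample rate.

    Parameters
    ----------
    labels
        Point labels, a subset of the stream kind's allowed label set.
    times
        Sample instants in seconds, uniformly spaced at ``1/rate``.
    points
        Mapping label -> ``(n, 3)`` array of positions in meters; missing
        samples are NaN rows.
    rate
        Sample rate in Hz.
    stream_kind
        ``"marker"`` or ``"camera"``.
    meta
        Free-form provenance (subject id, trial id, exercise name, ...).
    """

    labels: List[str]
    times: np.ndarray
    points: Dict[str, np.ndarray]
    rate: float
    stream_kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.stream_kind not in _ALLOWED:
            raise ValueError(f"unknown stream_kind {self.stream_kind!r}")
        bad = [lab for lab in self.labels if lab not in _ALLOWED[self.stream_kind]]
        if bad:
            raise ValueError(
                f"labels {bad} not allowed for stream kind {self.stream_kind!r}"
            )
        n = len(self.times)
        for lab in self.labels:
            if lab not in self.points:
                raise ValueError(f"missing point data for label {lab!r}")
            arr = np.asarray(self.points[lab], dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(
                    f"label {lab!r}: expected shape {(n, 3)}, got {arr.shape}"
                )
            self.points[lab] = arr
        if n > 1:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - 1.0 / self.rate) > 1e-9):
                raise ValueError("time spacing does not match declared rate")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Dict[str, np.ndarray]:
        """Points at frame ``i`` (NaN rows included)."""
        return {lab: self.points[lab][i] for lab in self.labels}

    def missing_mask(self, label: str) -> np.ndarray:
        """Boolean mask of frames where ``label`` is missing."""
        return np.any(np.isnan(self.points[label]), axis=1)

    def with_points(self, labels, points, **meta) -> "TrajectorySet":
        """Copy with additional labeled point series."""
        new_labels = list(self.labels) + [l for l in labels if l not in self.labels]
        new_points = dict(self.points)
        new_points.update(points)
        return TrajectorySet(
            labels=new_labels,
            times=self.times.copy(),
            points=new_points,
            rate=self.rate,
            stream_kind=self.stream_kind,
            meta={**self.meta, **meta},
        )


@dataclass
class PoseTrajectory:
    """Generalized-coordinate time series in degrees.

    ``residual_rms`` (weighted RMS marker error, m) and ``flags`` (True where a
    frame was under-determined or clamped) are filled by the inverse-kinematics
    solver and left None for synthetic ground truth.
    """

    times: np.ndarray
    coordinates: Dict[str, np.ndarray]
    residual_rms: Optional[np.ndarray] = None
    flags: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        n = len(self.times)
        for name, series in self.coordinates.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"coordinate {name!r}: bad shape {arr.shape}")
            self.coordinates[name] = arr

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        if len(self.times) < 2:
            raise ValueError("rate undefined for a single-frame trajectory")
        return 1.0 / float(np.mean(np.diff(self.times)))

    def frame(self, i: int) -> Dict[str, float]:
        return {name: float(s[i]) for name, s in self.coordinates.items()}

    def matrix(self, names) -> np.ndarray:
        """Stack the named coordinate series into an ``(n, len(names))`` array."""
        return np.column_stack([self.coordinates[n] for n in names])

    def resampled(self, new_times: np.ndarray) -> "PoseTrajectory":
        """Linear interpolation of every coordinate onto ``new_times``."""
        new_times = np.asarray(new_times, dtype=float)
        coords = {
            name: np.interp(new_times, self.times, series)
            for name, series in self.coordinates.items()
        }
        return PoseTrajectory(times=new_times, coordinates=coords, meta=dict(self.meta))
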