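"""Data cleaning and preparation: joint centers, trial QC, static-pose scaling.

Mirrors the preparation stage of a two-pathway motion-capture comparison:

* joint centers are derived from bony landmarks (epicondyle / styloid
  midpoints; shoulder center as a regression offset from the acromion),
* trials failing quality control are excluded with a reason (marker streams:
  too many missing markers per segment; camera streams: anatomically
  impossible segment lengths or teleporting centers),
* per-segment scale factors are computed from a static neutral pose, with the
  sparse camera stream forced to scale the thorax uniformly,
* scapula and clavicle coordinates are prescribed from humeral elevation via
  a linear scapulohumeral-rhythm stand-in (the published regressions are not
  reprinted here; coefficients are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model_registry import GenericModel, marker_positions
from .trajectories import PoseTrajectory, TrajectorySet

__all__ = [
    "RegressionCoefficients",
    "QCReport",
    "ScaleSet",
    "default_regression",
    "estimate_joint_centers",
    "elevation_from_centers",
    "coordinate_elevation_from_humerothoracic",
    "qc_marker_trial",
    "qc_camera_trial",
    "compute_scales",
    "prescribe_scapula_clavicle",
    "SEGMENT_MARKER_GROUPS",
    "DEFAULT_SCALE_PAIRS",
]


@dataclass
class RegressionCoefficients:
    """Landmark-to-joint-center and elevation-to-girdle regression constants.

    ``shoulder_offset`` is a constant global-frame offset from the acromion to
    the glenohumeral center (an upright-thorax simplification of published
    regressions).  ``rhythm_slopes`` / ``rhythm_intercepts`` define each
    prescribed girdle coordinate as an affine function of humero-thoracic
    elevation, in degrees.
    """

    shoulder_offset: Tuple[float, float, float] = (0.0, -0.045, 0.0)
    rhythm_slopes: Dict[str, float] = field(default_factory=dict)
    rhythm_intercepts: Dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("a documented provenance string is required")
        vals = list(self.shoulder_offset) + list(self.rhythm_slopes.values()) + list(
            self.rhythm_intercepts.values()
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("regression coefficients must be finite")


#: Prescribed girdle coordinates, in chain order.
GIRDLE_COORDINATES = (
    "clav_protraction",
    "clav_elevation",
    "scap_protraction",
    "scap_upward_rotation",
    "scap_tilt",
)


def default_regression() -> RegressionCoefficients:
    """Default stand-in coefficients: a 1:2 scapulohumeral rhythm.

    Scapular upward rotation follows half the humeral elevation; the other
    girdle coordinates stay neutral.  These are configurable stand-ins, not
    reprinted literature values.
    """
    return RegressionCoefficients(
        shoulder_offset=(0.0, -0.045, 0.0),
        rhythm_slopes={c: (0.5 if c == "scap_upward_rotation" else 0.0) for c in GIRDLE_COORDINATES},
        rhythm_intercepts={c: 0.0 for c in GIRDLE_COORDINATES},
        provenance="linear scapulohumeral-rhythm stand-in (upward rotation = elevation/2)",
    )


# ---------------------------------------------------------------------------
# joint centers


def _midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 0.5 * (a + b)


def estimate_joint_centers(
    markers: TrajectorySet, coeffs: RegressionCoefficients
) -> TrajectorySet:
    """Append shoulder/elbow/wrist joint-center trajectories to a marker stream.

    Elbow center: midpoint of the epicondyle markers.  Wrist center: midpoint
    of the ulna-head and radial-styloid markers.  Shoulder center: acromion
    plus the regression offset.  Frames with a missing required landmark yield
    a missing center; a landmark absent for *all* frames is a hard error.
    """
    if markers.stream_kind != "marker":
        raise ValueError("joint-center estimation expects a marker stream")
    required = {
        "Elbow joint center": ("Epicondylus Medialis", "Epicondylus Lateralis"),
        "Wrist joint center": ("Head of the Ulna", "Styloid processes of radius"),
        "Shoulder joint center": ("Acromion",),
    }
    for center, labs in required.items():
        for lab in labs:
            if lab not in markers.labels:
                raise ValueError(f"cannot estimate {center}: label {lab!r} absent")
            if np.all(markers.missing_mask(lab)):
                raise ValueError(
                    f"cannot estimate {center}: label {lab!r} missing on all frames"
                )
    centers = {
        "Elbow joint center": _midpoint(
            markers.points["Epicondylus Medialis"],
            markers.points["Epicondylus Lateralis"],
        ),
        "Wrist joint center": _midpoint(
            markers.points["Head of the Ulna"],
            markers.points["Styloid processes of radius"],
        ),
        "Shoulder joint center": markers.points["Acromion"]
        + np.asarray(coeffs.shoulder_offset),
    }
    return markers.with_points(list(centers), centers)


def coordinate_elevation_from_humerothoracic(
    theta_deg: np.ndarray, coeffs: RegressionCoefficients
) -> np.ndarray:
    """Glenohumeral elevation coordinate from the humerothoracic angle.

    The center-based elevation angle measures the humerus relative to the
    thorax, i.e. the elevation coordinate plus the (colinear) scapular upward
    rotation.  With the rhythm ``s = slope * e + intercept`` the coordinate is
    recovered as ``e = (theta - intercept) / (1 + slope)``.
    """
    slope = coeffs.rhythm_slopes.get("scap_upward_rotation", 0.0)
    intercept = coeffs.rhythm_intercepts.get("scap_upward_rotation", 0.0)
    return (np.asarray(theta_deg, dtype=float) - intercept) / (1.0 + slope)


def elevation_from_centers(stream: TrajectorySet) -> np.ndarray:
    """Humero-thoracic elevation angle (deg) from shoulder and elbow centers.

    Angle between the shoulder-to-elbow vector and the global downward axis;
    0 deg for a hanging arm.  NaN where a center is missing.
    """
    sh = stream.points["Shoulder joint center"]
    el = stream.points["Elbow joint center"]
    v = el - sh
    norm = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(-v[:, 1] / norm, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


# ---------------------------------------------------------------------------
# quality control

#: Marker labels per rigid segment for the 3-markers-per-segment rule.  The
#: hand carries a single marker by design and is exempt from the rule.
SEGMENT_MARKER_GROUPS: Dict[str, Tuple[str, ...]] = {
    "thorax": (
        "Incisura Jugularis",
        "Processus Xiphoideus",
        "Cervical Vertebrae 7",
        "Thoracic Vertebrae 10",
    ),
    "upper_arm": (
        "Acromion",
        "Epicondylus Medialis",
        "Epicondylus Lateralis",
        "Upper arm",
    ),
    "lower_arm": ("Head of the Ulna", "Styloid processes of radius", "Lower arm"),
}


@dataclass
class QCReport:
    trial_id: str
    included: bool
    reason: str  # ok | too_many_missing_markers | unrealistic_pose
    offending: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.reason == "ok") != self.included:
            raise ValueError("reason 'ok' must coincide with inclusion")


def qc_marker_trial(
    markers: TrajectorySet, max_bad_fraction: float = 0.05
) -> QCReport:
    """Exclude a marker trial when a segment drops below 3 visible markers.

    A segment frame is bad when fewer than three of its markers are present;
    the trial is excluded when any segment is bad on more than
    ``max_bad_fraction`` of frames.
    """
    if markers.stream_kind != "marker":
        raise ValueError("qc_marker_trial expects a marker stream")
    trial_id = str(markers.meta.get("trial_id", ""))
    offending = {}
    for seg, labs in SEGMENT_MARKER_GROUPS.items():
        present = [lab for lab in labs if lab in markers.labels]
        n_visible = np.zeros(markers.n_frames, dtype=int)
        for lab in present:
            n_visible += ~markers.missing_mask(lab)
        bad = n_visible < 3
        frac = float(np.mean(bad)) if markers.n_frames else 0.0
        if frac > max_bad_fraction:
            offending[seg] = {"bad_fraction": frac, "n_bad_frames": int(bad.sum())}
    if offending:
        return QCReport(trial_id, False, "too_many_missing_markers", offending)
    return QCReport(trial_id, True, "ok")


def qc_camera_trial(
    centers: TrajectorySet,
    min_segment_length: float = 0.15,
    max_segment_length: float = 0.6,
    max_speed: float = 10.0,
) -> QCReport:
    """Exclude camera trials with impossible skeletons or teleporting centers.

    Flags a trial when the median upper-arm or forearm inter-center length
    falls outside (``min_segment_length``, ``max_segment_length``) meters
    (strict inequalities), or when the median frame-to-frame center speed
    exceeds ``max_speed`` m/s.
    """
    if centers.stream_kind != "camera":
        raise ValueError("qc_camera_trial expects a camera stream")
    trial_id = str(centers.meta.get("trial_id", ""))
    offending = {}
    pairs = {
        "upper_arm": ("Shoulder joint center", "Elbow joint center"),
        "forearm": ("Elbow joint center", "Wrist joint center"),
    }
    for seg, (a, b) in pairs.items():
        d = np.linalg.norm(centers.points[a] - centers.points[b], axis=1)
        med = float(np.nanmedian(d))
        # strict inequalities: a median exactly at a bound passes
        if med < min_segment_length or med > max_segment_length:
            offending[seg] = {"median_length_m": med}
    if centers.n_frames > 1:
        speeds = []
        for lab in centers.labels:
            v = np.diff(centers.points[lab], axis=0) * centers.rate
            speeds.append(np.linalg.norm(v, axis=1))
        med_speed = float(np.nanmedian(np.concatenate(speeds)))
        if med_speed > max_speed:
            offending["speed"] = {"median_speed_m_s": med_speed}
    if offending:
        return QCReport(trial_id, False, "unrealistic_pose", offending)
    return QCReport(trial_id, True, "ok")


# ---------------------------------------------------------------------------
# scaling

#: Default virtual-marker pairs per segment and stream kind.  Each entry is
#: (label_a, label_b, axes): the measured/generic distance ratio scales the
#: listed axes of the segment; axes with no pair fall back to the mean factor.
#: The camera stream's single thorax pair forces the uniform-thorax rule.
DEFAULT_SCALE_PAIRS: Dict[str, Dict[str, List[Tuple[str, str, Tuple[str, ...]]]]] = {
    "marker": {
        "thorax": [
            ("Cervical Vertebrae 7", "Thoracic Vertebrae 10", ("y",)),
            ("Incisura Jugularis", "Cervical Vertebrae 7", ("z",)),
        ],
        "clavicle": [("Incisura Jugularis", "Acromion", ("x", "y", "z"))],
        "scapula": [("Incisura Jugularis", "Acromion", ("x", "y", "z"))],
        "humerus": [
            ("Epicondylus Medialis", "Epicondylus Lateralis", ("x",)),
            ("Shoulder joint center", "Elbow joint center", ("y", "z")),
        ],
        "forearm": [
            ("Head of the Ulna", "Styloid processes of radius", ("x",)),
            ("Elbow joint center", "Wrist joint center", ("y", "z")),
        ],
        "hand": [
            ("Wrist joint center", "Interphalangealis proximal III", ("x", "y", "z"))
        ],
    },
    "camera": {
        "thorax": [("Mid spine", "Mid thorax", ("x", "y", "z"))],
        "clavicle": [("Mid thorax", "Shoulder joint center", ("x", "y", "z"))],
        "scapula": [("Mid thorax", "Shoulder joint center", ("x", "y", "z"))],
        "humerus": [("Shoulder joint center", "Elbow joint center", ("x", "y", "z"))],
        "forearm": [("Elbow joint center", "Wrist joint center", ("x", "y", "z"))],
        "hand": [("Elbow joint center", "Wrist joint center", ("x", "y", "z"))],
    },
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class ScaleSet:
    """Per-segment 3-D scale factors derived from a static pose."""

    factors: Dict[str, np.ndarray]
    method: str  # per_axis | uniform
    static_pose_source: str = ""

    def __post_init__(self) -> None:
        for seg, f in self.factors.items():
            f = np.asarray(f, dtype=float)
            if np.any(f <= 0):
                raise ValueError(f"segment {seg!r}: scale factors must be > 0")
            self.factors[seg] = f


def compute_scales(
    static: TrajectorySet,
    model: GenericModel,
    pairs: Optional[Mapping[str, Sequence[Tuple[str, str, Tuple[str, ...]]]]] = None,
) -> ScaleSet:
    """Per-segment scale factors from a static trial.

    Each configured virtual-marker pair contributes the ratio of the mean
    measured distance to the generic-model distance in the neutral pose.  The
    marker stream resolves separate axes where its pairs allow; the camera
    stream's pairs are all isotropic, so in particular the thorax is scaled
    uniformly from its single length pair.
    """
    if pairs is None:
        pairs = DEFAULT_SCALE_PAIRS[static.stream_kind]
    neutral = {c: 0.0 for c in model.chain.coordinate_names}
    generic = marker_positions(model, neutral)
    factors: Dict[str, np.ndarray] = {}
    per_axis = False
    for seg, seg_pairs in pairs.items():
        axis_factors: Dict[int, List[float]] = {0: [], 1: [], 2: []}
        all_factors: List[float] = []
        for lab_a, lab_b, axes in seg_pairs:
            if lab_a not in static.labels or lab_b not in static.labels:
                continue
            # average positions over the static trial before taking the
            # distance: less noise-induced upward distance bias than
            # averaging per-frame distances
            pa = np.nanmean(static.points[lab_a], axis=0)
            pb = np.nanmean(static.points[lab_b], axis=0)
            d_meas = float(np.linalg.norm(pa - pb))
            d_gen = float(np.linalg.norm(generic[lab_a] - generic[lab_b]))
            if d_gen < 1e-6:
                raise ValueError(
                    f"degenerate generic distance for pair ({lab_a!r}, {lab_b!r})"
                )
            if not np.isfinite(d_meas):
                continue
            f = d_meas / d_gen
            all_factors.append(f)
            if len(axes) < 3:
                per_axis = True
            for ax in axes:
                axis_factors[_AXIS_INDEX[ax]].append(f)
        if not all_factors:
            factors[seg] = np.ones(3)
            continue
        fallback = float(np.mean(all_factors))
        factors[seg] = np.array(
            [
                float(np.mean(axis_factors[i])) if axis_factors[i] else fallback
                for i in range(3)
            ]
        )
    return ScaleSet(
        factors=factors,
        method="per_axis" if per_axis else "uniform",
        static_pose_source=str(static.meta.get("trial_id", "")),
    )


# ---------------------------------------------------------------------------
# prescribed girdle coordinates


def prescribe_scapula_clavicle(
    pose_partial: PoseTrajectory, coeffs: RegressionCoefficients
) -> PoseTrajectory:
    """Fill the prescribed girdle coordinates from humeral elevation.

    Each of the five clavicle/scapula coordinates is an affine function of the
    ``shoulder_elevation`` series of ``pose_partial``; existing coordinates
    are carried over unchanged.
    """
    if "shoulder_elevation" not in pose_partial.coordinates:
        raise KeyError("pose_partial must provide 'shoulder_elevation'")
    elev = pose_partial.coordinates["shoulder_elevation"]
    coords = dict(pose_partial.coordinates)
    for name in GIRDLE_COORDINATES:
        slope = coeffs.rhythm_slopes.get(name, 0.0)
        intercept = coeffs.rhythm_intercepts.get(name, 0.0)
        coords[name] = intercept + slope * elev
    return PoseTrajectory(
        times=pose_partial.times.copy(),
        coordinates=coords,
        meta=dict(pose_partial.meta),
    )
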