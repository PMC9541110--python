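"""Generic musculoskeletal model: kinematic chain, muscle registry, forward kinematics.

The model is a simplified thoracoscapular shoulder + elbow chain:

* thorax fixed at the origin (world frame: X right, Y up, Z forward; gravity -Y),
* clavicle and scapula driven by prescribed coordinates (scapulohumeral rhythm),
* a 3-coordinate glenohumeral joint (elevation plane / elevation / axial rotation,
  intrinsic Y-Z-Y), elbow flexion, forearm pronation-supination, rigid wrist.

The muscle registry holds the published maximum isometric force, optimal fiber
length, tendon slack length and pennation angle of 33 aggregated muscle bundles
of the shoulder and elbow.  Muscle geometry is a configurable straight-line
path-point asset; it is plausible rather than anatomically exact, which is
sufficient here because every force comparison in the pipeline is internal
(camera stream versus marker stream through the same geometry).

All public interfaces use degrees; rotation internals are radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "MuscleParameters",
    "MuscleGeometry",
    "SegmentInertia",
    "Coordinate",
    "Joint",
    "KinematicChain",
    "GenericModel",
    "ModelAssetError",
    "load_default_model",
    "group_f_max",
    "chain_forward_kinematics",
    "marker_positions",
    "path_points_world",
    "model_to_dict",
    "save_model",
]


class ModelAssetError(RuntimeError):
    """Raised when a model asset file is missing or malformed."""


@dataclass(frozen=True)
class MuscleParameters:
    """One registry entry: published Hill-type parameters of a muscle bundle."""

    name: str
    group: str
    f_max_iso: float  # N
    l_opt: float  # m, optimal fiber length
    l_ts: float  # m, tendon slack length
    alpha_penn: float  # deg, pennation angle
    bundle_ids: str  # provenance label of the aggregated bundles

    def __post_init__(self) -> None:
        if self.f_max_iso <= 0:
            raise ValueError(f"{self.name}: f_max_iso must be > 0")
        if self.l_opt <= 0:
            raise ValueError(f"{self.name}: l_opt must be > 0")
        if self.l_ts < 0:
            raise ValueError(f"{self.name}: l_ts must be >= 0")
        if not 0 <= self.alpha_penn < 90:
            raise ValueError(f"{self.name}: pennation must be in [0, 90) deg")

    @property
    def base_name(self) -> str:
        """Muscle name with the head/region suffix removed (group label)."""
        if self.group and self.name.lower().endswith(" " + self.group.lower()):
            return self.name[: -(len(self.group) + 1)]
        return self.name


@dataclass(frozen=True)
class MuscleGeometry:
    """Straight-line muscle path: ordered (segment, local offset) points."""

    muscle_name: str
    path_points: Tuple[Tuple[str, Tuple[float, float, float]], ...]
    spanned_coordinates: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.path_points) < 2:
            raise ValueError(f"{self.muscle_name}: need >= 2 path points")
        if self.path_points[0][0] == self.path_points[-1][0]:
            raise ValueError(
                f"{self.muscle_name}: first and last path points must attach "
                "to different segments"
            )


@dataclass(frozen=True)
class SegmentInertia:
    segment_name: str
    mass: float  # kg
    com_offset: Tuple[float, float, float]  # m, segment-local
    inertia_diag: Tuple[float, float, float]  # kg m^2, principal moments

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"{self.segment_name}: mass must be >= 0")
        if any(i < 0 for i in self.inertia_diag):
            raise ValueError(f"{self.segment_name}: inertia must be >= 0")


@dataclass(frozen=True)
class Coordinate:
    name: str
    axis: Tuple[float, float, float]  # rotation axis, local frame
    range_deg: Tuple[float, float]
    prescribed: bool = False


@dataclass(frozen=True)
class Joint:
    name: str
    parent: str
    child: str
    offset: Tuple[float, float, float]  # m, in the parent frame
    coordinates: Tuple[Coordinate, ...] = ()


@dataclass
class KinematicChain:
    """Tree-structured chain, root first; coordinate order follows joint order."""

    segments: List[str]
    joints: List[Joint]

    def __post_init__(self) -> None:
        children = [j.child for j in self.joints]
        if len(set(children)) != len(children):
            raise ValueError("chain is not a tree: duplicate child segment")
        if set(children) != set(self.segments) - {self.segments[0]}:
            raise ValueError("every non-root segment needs exactly one parent joint")
        names = [c.name for j in self.joints for c in j.coordinates]
        if len(set(names)) != len(names):
            raise ValueError("coordinate names must be unique")
        self._coords: List[Coordinate] = [
            c for j in self.joints for c in j.coordinates
        ]
        self._index = {c.name: i for i, c in enumerate(self._coords)}
        # flattened evaluation plan for fast forward kinematics
        plan = []
        k = 0
        for j in self.joints:
            axes = []
            for c in j.coordinates:
                axes.append((k, np.asarray(c.axis, dtype=float)))
                k += 1
            plan.append((j.parent, j.child, np.asarray(j.offset, dtype=float), axes))
        self._plan = plan
        # array-form plan for the compiled kernel (joints are ordered with
        # parents before children, so child j maps to segment index j+1)
        seg_idx = {s: i for i, s in enumerate(self.segments)}
        self._kernel_ok = all(
            seg_idx[j.child] == i + 1 for i, j in enumerate(self.joints)
        )
        self._parents = np.array([seg_idx[j.parent] for j in self.joints], dtype=np.int64)
        self._offsets = np.array([j.offset for j in self.joints], dtype=float)
        counts = [len(j.coordinates) for j in self.joints]
        self._coord_start = np.array(np.concatenate([[0], np.cumsum(counts)[:-1]]), dtype=np.int64)
        self._coord_count = np.array(counts, dtype=np.int64)
        self._axes = (
            np.array([list(c.axis) for c in self._coords], dtype=float)
            if self._coords
            else np.zeros((0, 3))
        )

    @property
    def coordinates(self) -> List[Coordinate]:
        return list(self._coords)

    @property
    def coordinate_names(self) -> List[str]:
        return [c.name for c in self._coords]

    @property
    def free_coordinates(self) -> List[str]:
        return [c.name for c in self._coords if not c.prescribed]

    @property
    def prescribed_coordinates(self) -> List[str]:
        return [c.name for c in self._coords if c.prescribed]

    def coordinate(self, name: str) -> Coordinate:
        try:
            return self._coords[self._index[name]]
        except KeyError:
            raise KeyError(
                f"unknown coordinate {name!r}; chain has {self.coordinate_names}"
            ) from None

    def q_array(self, coords: Mapping[str, float]) -> np.ndarray:
        """Coordinate mapping (deg) -> ordered array (deg); errors name the gap."""
        out = np.empty(len(self._coords))
        for i, c in enumerate(self._coords):
            if c.name not in coords:
                raise KeyError(f"missing coordinate {c.name!r}")
            out[i] = coords[c.name]
        return out


@dataclass
class GenericModel:
    """Bundle of chain, muscle registry, geometry, inertia and virtual markers."""

    chain: KinematicChain
    muscles: List[MuscleParameters]
    geometry: List[MuscleGeometry]
    inertia: List[SegmentInertia]
    virtual_markers: Dict[str, Tuple[str, Tuple[float, float, float]]]

    def __post_init__(self) -> None:
        geo = {g.muscle_name for g in self.geometry}
        missing = [m.name for m in self.muscles if m.name not in geo]
        if missing:
            raise ValueError(f"muscles without geometry: {missing}")
        coord_names = set(self.chain.coordinate_names)
        for g in self.geometry:
            bad = set(g.spanned_coordinates) - coord_names
            if bad:
                raise ValueError(f"{g.muscle_name}: unknown spanned coordinates {bad}")
            for seg, _ in g.path_points:
                if seg not in self.chain.segments:
                    raise ValueError(f"{g.muscle_name}: unknown segment {seg!r}")
        for label, (seg, _) in self.virtual_markers.items():
            if seg not in self.chain.segments:
                raise ValueError(f"marker {label!r}: unknown segment {seg!r}")
        self._muscle_index = {m.name: m for m in self.muscles}
        self._geometry_index = {g.muscle_name: g for g in self.geometry}
        self._inertia_index = {s.segment_name: s for s in self.inertia}

    def muscle(self, name: str) -> MuscleParameters:
        return self._muscle_index[name]

    def muscle_geometry(self, name: str) -> MuscleGeometry:
        return self._geometry_index[name]

    def segment_inertia(self, name: str) -> Optional[SegmentInertia]:
        return self._inertia_index.get(name)

    @property
    def muscle_names(self) -> List[str]:
        return [m.name for m in self.muscles]

    def scaled(self, factors: Mapping[str, Sequence[float]]) -> "GenericModel":
        """Return a copy with segment-local geometry scaled per axis.

        ``factors`` maps segment name to a 3-vector of scale factors.  Joint
        offsets live in the parent frame and are scaled by the parent's
        factors; markers, muscle path points and mass-center offsets are
        scaled by their own segment's factors.  Masses and inertia moments
        are left unchanged (subject mass is a config input, not a scale output).
        """

        def fac(seg: str) -> np.ndarray:
            return np.asarray(factors.get(seg, (1.0, 1.0, 1.0)), dtype=float)

        joints = [
            replace(j, offset=tuple(np.asarray(j.offset) * fac(j.parent)))
            for j in self.chain.joints
        ]
        chain = KinematicChain(segments=list(self.chain.segments), joints=joints)
        geometry = [
            MuscleGeometry(
                muscle_name=g.muscle_name,
                path_points=tuple(
                    (seg, tuple(np.asarray(off) * fac(seg)))
                    for seg, off in g.path_points
                ),
                spanned_coordinates=g.spanned_coordinates,
            )
            for g in self.geometry
        ]
        inertia = [
            replace(s, com_offset=tuple(np.asarray(s.com_offset) * fac(s.segment_name)))
            for s in self.inertia
        ]
        markers = {
            lab: (seg, tuple(np.asarray(off) * fac(seg)))
            for lab, (seg, off) in self.virtual_markers.items()
        }
        return GenericModel(
            chain=chain,
            muscles=list(self.muscles),
            geometry=geometry,
            inertia=inertia,
            virtual_markers=markers,
        )


# ---------------------------------------------------------------------------
# forward kinematics


def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x = axis[0]
    y = axis[1]
    z = axis[2]
    c = math.cos(angle_rad)
    s = math.sin(angle_rad)
    t = 1.0 - c
    out = np.empty((3, 3))
    out[0, 0] = t * x * x + c
    out[0, 1] = t * x * y - s * z
    out[0, 2] = t * x * z + s * y
    out[1, 0] = t * x * y + s * z
    out[1, 1] = t * y * y + c
    out[1, 2] = t * y * z - s * x
    out[2, 0] = t * x * z - s * y
    out[2, 1] = t * y * z + s * x
    out[2, 2] = t * z * z + c
    return out


def chain_forward_kinematics(
    chain: KinematicChain, coords: Mapping[str, float]
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Global pose (rotation matrix, origin position) per segment.

    ``coords`` must supply every chain coordinate, in degrees; a missing one
    raises ``KeyError`` naming it.
    """
    q = chain.q_array(coords)
    return fk_from_array(chain, q)


_EYE3 = np.eye(3)
_ZERO3 = np.zeros(3)

try:  # compiled forward-kinematics kernel; plain numpy otherwise
    from numba import njit as _njit

    @_njit(cache=True)
    def _fk_kernel(q_rad, parents, offsets, coord_start, coord_count, axes):  # pragma: no cover
        n_seg = parents.shape[0] + 1
        rot = np.empty((n_seg, 3, 3))
        pos = np.empty((n_seg, 3))
        for i in range(3):
            pos[0, i] = 0.0
            for j in range(3):
                rot[0, i, j] = 1.0 if i == j else 0.0
        for j in range(parents.shape[0]):
            par = parents[j]
            child = j + 1
            for i in range(3):
                pos[child, i] = (
                    pos[par, i]
                    + rot[par, i, 0] * offsets[j, 0]
                    + rot[par, i, 1] * offsets[j, 1]
                    + rot[par, i, 2] * offsets[j, 2]
                )
            cur = rot[par].copy()
            for t in range(coord_count[j]):
                k = coord_start[j] + t
                x = axes[k, 0]
                y = axes[k, 1]
                z = axes[k, 2]
                c = np.cos(q_rad[k])
                s = np.sin(q_rad[k])
                u = 1.0 - c
                a00 = u * x * x + c
                a01 = u * x * y - s * z
                a02 = u * x * z + s * y
                a10 = u * x * y + s * z
                a11 = u * y * y + c
                a12 = u * y * z - s * x
                a20 = u * x * z - s * y
                a21 = u * y * z + s * x
                a22 = u * z * z + c
                nxt = np.empty((3, 3))
                for i in range(3):
                    nxt[i, 0] = cur[i, 0] * a00 + cur[i, 1] * a10 + cur[i, 2] * a20
                    nxt[i, 1] = cur[i, 0] * a01 + cur[i, 1] * a11 + cur[i, 2] * a21
                    nxt[i, 2] = cur[i, 0] * a02 + cur[i, 1] * a12 + cur[i, 2] * a22
                cur = nxt
            rot[child] = cur
        return rot, pos

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def fk_from_array(
    chain: KinematicChain, q_deg: np.ndarray
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Forward kinematics from an ordered coordinate array (degrees)."""
    return fk_rad(chain, np.radians(np.asarray(q_deg, dtype=float)))


def fk_rad(
    chain: KinematicChain, q_rad: np.ndarray
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Forward kinematics from an ordered coordinate array in radians."""
    if _HAVE_NUMBA and chain._kernel_ok:
        rot, pos = _fk_kernel(
            np.asarray(q_rad, dtype=float),
            chain._parents,
            chain._offsets,
            chain._coord_start,
            chain._coord_count,
            chain._axes,
        )
        return {seg: (rot[i], pos[i]) for i, seg in enumerate(chain.segments)}
    poses: Dict[str, Tuple[np.ndarray, np.ndarray]] = {
        chain.segments[0]: (_EYE3, _ZERO3)
    }
    for parent, child, offset, axes in chain._plan:
        r_p, p_p = poses[parent]
        p = p_p + r_p @ offset
        r = r_p
        for k, axis in axes:
            r = r @ _axis_rotation(axis, q_rad[k])
        poses[child] = (r, p)
    return poses


def marker_positions(
    model: GenericModel,
    coords: Mapping[str, float],
    labels: Optional[Sequence[str]] = None,
) -> Dict[str, np.ndarray]:
    """World positions of the model's virtual markers at a pose."""
    poses = chain_forward_kinematics(model.chain, coords)
    labels = list(model.virtual_markers) if labels is None else list(labels)
    out = {}
    for lab in labels:
        seg, off = model.virtual_markers[lab]
        r, p = poses[seg]
        out[lab] = p + r @ np.asarray(off)
    return out


def path_points_world(
    geometry: MuscleGeometry, poses: Mapping[str, Tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """World coordinates of a muscle path, ``(n_points, 3)``."""
    pts = np.empty((len(geometry.path_points), 3))
    for i, (seg, off) in enumerate(geometry.path_points):
        r, p = poses[seg]
        pts[i] = p + r @ np.asarray(off)
    return pts


# ---------------------------------------------------------------------------
# registry queries


def group_f_max(muscle_base_name: str, model: GenericModel) -> float:
    """Total maximum isometric force of all heads sharing a base name.

    ``"Infraspinatus"`` sums the superior and inferior heads; a single-entry
    name such as ``"Teres minor"`` returns its own value.  The per-head sum is
    the normalizer of the %Fmax error metric for aggregated report rows.
    """
    total = 0.0
    found = False
    for m in model.muscles:
        if m.name == muscle_base_name or m.name.startswith(muscle_base_name + " "):
            total += m.f_max_iso
            found = True
    if not found:
        bases = sorted({m.name.rsplit(" ", 1)[0] for m in model.muscles})
        raise KeyError(
            f"unknown muscle base name {muscle_base_name!r}; known bases "
            f"include {bases}"
        )
    return total


# ---------------------------------------------------------------------------
# asset (de)serialization


def _chain_from_dict(d: dict) -> KinematicChain:
    joints = []
    for jd in d["joints"]:
        coords = tuple(
            Coordinate(
                name=cd["name"],
                axis=tuple(cd["axis"]),
                range_deg=tuple(cd["range"]),
                prescribed=bool(cd.get("prescribed", False)),
            )
            for cd in jd.get("coordinates", [])
        )
        joints.append(
            Joint(
                name=jd["name"],
                parent=jd["parent"],
                child=jd["child"],
                offset=tuple(jd["offset"]),
                coordinates=coords,
            )
        )
    return KinematicChain(segments=list(d["segments"]), joints=joints)


def model_from_dict(d: dict) -> GenericModel:
    chain = _chain_from_dict(d["chain"])
    muscles = [
        MuscleParameters(
            name=m["name"],
            group=m.get("group", ""),
            f_max_iso=float(m["f_max_iso"]),
            l_opt=float(m["l_opt"]),
            l_ts=float(m["l_ts"]),
            alpha_penn=float(m["alpha_penn"]),
            bundle_ids=str(m.get("bundle_ids", "")),
        )
        for m in d["muscles"]
    ]
    geometry = [
        MuscleGeometry(
            muscle_name=g["muscle"],
            path_points=tuple((p["segment"], tuple(p["offset"])) for p in g["path"]),
            spanned_coordinates=tuple(g["spanned_coordinates"]),
        )
        for g in d["geometry"]
    ]
    inertia = [
        SegmentInertia(
            segment_name=s["segment"],
            mass=float(s["mass"]),
            com_offset=tuple(s["com_offset"]),
            inertia_diag=tuple(s["inertia_diag"]),
        )
        for s in d["inertia"]
    ]
    markers = {
        lab: (spec["segment"], tuple(spec["offset"]))
        for lab, spec in d["virtual_markers"].items()
    }
    return GenericModel(
        chain=chain,
        muscles=muscles,
        geometry=geometry,
        inertia=inertia,
        virtual_markers=markers,
    )


def model_to_dict(model: GenericModel) -> dict:
    return {
        "chain": {
            "segments": list(model.chain.segments),
            "joints": [
                {
                    "name": j.name,
                    "parent": j.parent,
                    "child": j.child,
                    "offset": list(j.offset),
                    "coordinates": [
                        {
                            "name": c.name,
                            "axis": list(c.axis),
                            "range": list(c.range_deg),
                            "prescribed": c.prescribed,
                        }
                        for c in j.coordinates
                    ],
                }
                for j in model.chain.joints
            ],
        },
        "muscles": [
            {
                "name": m.name,
                "group": m.group,
                "f_max_iso": m.f_max_iso,
                "l_opt": m.l_opt,
                "l_ts": m.l_ts,
                "alpha_penn": m.alpha_penn,
                "bundle_ids": m.bundle_ids,
            }
            for m in model.muscles
        ],
        "geometry": [
            {
                "muscle": g.muscle_name,
                "path": [
                    {"segment": seg, "offset": list(off)} for seg, off in g.path_points
                ],
                "spanned_coordinates": list(g.spanned_coordinates),
            }
            for g in model.geometry
        ],
        "inertia": [
            {
                "segment": s.segment_name,
                "mass": s.mass,
                "com_offset": list(s.com_offset),
                "inertia_diag": list(s.inertia_diag),
            }
            for s in model.inertia
        ],
        "virtual_markers": {
            lab: {"segment": seg, "offset": list(off)}
            for lab, (seg, off) in model.virtual_markers.items()
        },
    }


def save_model(model: GenericModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> GenericModel:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ModelAssetError(f"model asset not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ModelAssetError(f"model asset {path} is not valid YAML: {exc}") from None
    if not isinstance(data, dict):
        raise ModelAssetError(f"model asset {path} is empty or malformed")
    try:
        return model_from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelAssetError(f"model asset {path} is incomplete: {exc}") from None


def load_default_model(path=None) -> GenericModel:
    """Load the packaged default model asset (or an override path)."""
    if path is not None:
        return load_model(path)
    ref = resources.files("camforce").joinpath("data/default_model.yaml")
    try:
        with resources.as_file(ref) as p:
            return load_model(p)
    except FileNotFoundError:
        raise ModelAssetError(
            "packaged asset data/default_model.yaml is missing"
        ) from None
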