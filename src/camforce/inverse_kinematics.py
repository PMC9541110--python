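"""Per-frame weighted least-squares inverse kinematics.

Each frame solves for the chain coordinates that minimize

    sum_l w_l ||x_model,l - x_exp,l||^2
  + w_angle * sum_presc (q - q_presc)^2
  + sum_c w_prior,c * q_c^2

over all chain coordinates, where the second term tracks the prescribed
clavicle/scapula coordinates (supplied by the scapulohumeral-rhythm
regression) and the third term is a small quadratic prior toward neutral for
coordinates that sparse joint-center input cannot observe (humeral axial
rotation, forearm pronation; the elevation plane gets a weaker prior for
low-elevation stability).  Marker terms are in meters, angle terms in
radians.  The identical solver path serves both stream kinds; only the
label-to-virtual-marker correspondence differs.

The per-frame solver is a Levenberg-Marquardt iteration warm-started from the
previous frame; joint limits are applied as a soft clamp with a flag rather
than hard constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .model_registry import GenericModel, fk_rad
from .trajectories import PoseTrajectory, TrajectorySet

__all__ = ["IKSettings", "solve_frame", "solve_trajectory"]

_DEG = math.degrees(1.0)


@dataclass
class IKSettings:
    """Weights and solver settings for the weighted least-squares pose fit."""

    marker_weights: Dict[str, float] = field(default_factory=dict)
    default_marker_weight: float = 1.0
    angle_weight: float = 10.0  # tracking weight of prescribed coordinates (rad^2)
    prior_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "shoulder_rotation": 0.01,
            "forearm_rotation": 0.01,
            "shoulder_plane": 0.001,
        }
    )
    max_iterations: int = 100
    convergence_tol: float = 1e-6  # m
    initial_pose: Dict[str, float] = field(default_factory=dict)

    def weight(self, label: str) -> float:
        return self.marker_weights.get(label, self.default_marker_weight)

    def validate(self, labels) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if not any(self.weight(lab) > 0 for lab in labels):
            raise ValueError("at least one marker weight must be positive")


class _FrameProblem:
    """Precompiled residual evaluation for one frame's usable markers.

    Marker positions are evaluated per segment group (one matrix product per
    segment) rather than per marker.
    """

    def __init__(
        self,
        chain,
        groups,  # list of (segment, offsets (k,3), sqrt-weights (k,), exp (k,3))
        presc_idx: np.ndarray,
        presc_targets_rad: np.ndarray,
        prior_idx: np.ndarray,
        prior_w_sqrt: np.ndarray,
        angle_weight: float,
        n_marker_rows: int,
    ):
        self.chain = chain
        self.groups = groups
        self.presc_idx = presc_idx
        self.presc_targets = presc_targets_rad
        self.prior_idx = prior_idx
        self.prior_w_sqrt = prior_w_sqrt
        self.sqrt_aw = math.sqrt(angle_weight)
        self.n_rows = 3 * n_marker_rows + len(presc_idx) + len(prior_idx)
        self.n_marker_rows = n_marker_rows

    def __call__(self, q_rad: np.ndarray) -> np.ndarray:
        poses = fk_rad(self.chain, q_rad)
        res = np.empty(self.n_rows)
        k = 0
        for seg, offs, sw, exp in self.groups:
            r, p = poses[seg]
            block = (offs @ r.T + p - exp) * sw[:, None]
            nk = block.size
            res[k : k + nk] = block.ravel()
            k += nk
        np_ = len(self.presc_idx)
        if np_:
            res[k : k + np_] = self.sqrt_aw * (q_rad[self.presc_idx] - self.presc_targets)
            k += np_
        if len(self.prior_idx):
            res[k:] = self.prior_w_sqrt * q_rad[self.prior_idx]
        return res


def solve_frame(
    points: Mapping[str, np.ndarray],
    model: GenericModel,
    settings: IKSettings,
    warm_start: Mapping[str, float],
    prescribed: Optional[Mapping[str, float]] = None,
) -> Tuple[Dict[str, float], float, bool]:
    """Fit chain coordinates to one frame of labeled points.

    Returns ``(coordinates deg, weighted RMS marker residual m, flagged)``.
    Frames with fewer than three usable points are flagged and carry the warm
    start forward.  Deterministic given the warm start.
    """
    chain = model.chain
    names = chain.coordinate_names
    prescribed = prescribed or {}
    usable = [
        lab
        for lab in points
        if lab in model.virtual_markers
        and settings.weight(lab) > 0
        and not np.any(np.isnan(points[lab]))
    ]
    q0 = np.radians(chain.q_array(warm_start))
    if len(usable) < 3:
        return {n: math.degrees(q) for n, q in zip(names, q0)}, float("nan"), True

    idx = {n: i for i, n in enumerate(names)}
    groups = _segment_groups(model, settings, points, usable)
    presc_idx = np.array([idx[n] for n in prescribed], dtype=int)
    presc_targets = np.radians([prescribed[n] for n in prescribed])
    prior_items = [(idx[n], w) for n, w in settings.prior_weights.items() if n in idx and w > 0]
    prior_idx = np.array([i for i, _ in prior_items], dtype=int)
    prior_w = np.array([w for _, w in prior_items])

    fun = _FrameProblem(
        chain, groups, presc_idx, presc_targets,
        prior_idx, np.sqrt(prior_w), settings.angle_weight, len(usable),
    )
    q, res = _levenberg_marquardt(fun, q0, settings.max_iterations)
    flagged = False
    # soft clamp to coordinate ranges
    for i, coord in enumerate(chain.coordinates):
        lo, hi = math.radians(coord.range_deg[0]), math.radians(coord.range_deg[1])
        if q[i] < lo or q[i] > hi:
            q[i] = min(max(q[i], lo), hi)
            flagged = True
    marker_res = res[: 3 * len(usable)]
    total_w = sum(float(np.sum(sw**2)) for _, _, sw, _ in groups)
    rms = math.sqrt(float(marker_res @ marker_res) / total_w)
    return {n: math.degrees(v) for n, v in zip(names, q)}, rms, flagged


def _segment_groups(model, settings, points, usable):
    """Group usable markers by segment for vectorized residual evaluation."""
    by_seg: Dict[str, list] = {}
    for lab in usable:
        seg, off = model.virtual_markers[lab]
        by_seg.setdefault(seg, []).append(
            (np.asarray(off, dtype=float),
             math.sqrt(settings.weight(lab)),
             np.asarray(points[lab], dtype=float))
        )
    groups = []
    for seg, items in by_seg.items():
        offs = np.array([it[0] for it in items])
        sw = np.array([it[1] for it in items])
        exp = np.array([it[2] for it in items])
        groups.append((seg, offs, sw, exp))
    return groups


def _levenberg_marquardt(
    fun, x0: np.ndarray, max_iterations: int,
    gtol: float = 1e-12, xtol: float = 1e-12,
) -> Tuple[np.ndarray, np.ndarray]:
    """Damped Gauss-Newton iteration with a forward-difference Jacobian.

    Only improving steps are accepted, so the returned objective never
    exceeds the warm-start objective.
    """
    x = x0.astype(float).copy()
    r = fun(x)
    cost = float(r @ r)
    lam = 1e-4
    h = 1e-6  # rad FD step
    n = len(x)
    for _ in range(max_iterations):
        jac = np.empty((len(r), n))
        for j in range(n):
            xp = x.copy()
            xp[j] += h
            jac[:, j] = (fun(xp) - r) / h
        g = jac.T @ r
        if np.max(np.abs(g)) < gtol:
            break
        jtj = jac.T @ jac
        accepted = False
        for _ in range(20):
            try:
                step = np.linalg.solve(jtj + lam * np.eye(n), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            x_new = x + step
            r_new = fun(x_new)
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                x, r, cost = x_new, r_new, cost_new
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
            if lam > 1e10:
                break
        if not accepted or float(np.max(np.abs(step))) < xtol:
            break
    return x, r


def solve_trajectory(
    stream: TrajectorySet,
    model: GenericModel,
    settings: IKSettings,
    prescribed: PoseTrajectory,
) -> PoseTrajectory:
    """Frame-sequential inverse kinematics with previous-frame warm start.

    ``prescribed`` supplies the girdle coordinate targets (resampled to the
    stream's time base if needed).  The returned trajectory is marked
    unusable in ``meta['usable']`` when more than half the frames are flagged.
    """
    settings.validate(stream.labels)
    chain = model.chain
    names = chain.coordinate_names
    presc = (
        prescribed
        if np.array_equal(prescribed.times, stream.times)
        else prescribed.resampled(stream.times)
    )
    presc_names = [n for n in chain.prescribed_coordinates if n in presc.coordinates]

    warm: Dict[str, float] = {n: 0.0 for n in names}
    warm.update({n: float(presc.coordinates[n][0]) for n in presc_names})
    warm.update(settings.initial_pose)

    n = stream.n_frames
    coords = {name: np.empty(n) for name in names}
    residuals = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        targets = {m: float(presc.coordinates[m][i]) for m in presc_names}
        solved, rms, flagged = solve_frame(
            stream.frame(i), model, settings, warm, targets
        )
        for name in names:
            coords[name][i] = solved[name]
        residuals[i] = rms
        flags[i] = flagged
        if not flagged:
            warm = solved
    usable = bool(np.mean(flags) <= 0.5)
    meta = {
        **stream.meta,
        "usable": usable,
        "ik_settings": {
            "angle_weight": settings.angle_weight,
            "prior_weights": dict(settings.prior_weights),
            "default_marker_weight": settings.default_marker_weight,
        },
    }
    return PoseTrajectory(
        times=stream.times.copy(),
        coordinates=coords,
        residual_rms=residuals,
        flags=flags,
        meta=meta,
    )
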