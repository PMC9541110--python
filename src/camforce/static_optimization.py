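"""Per-frame muscle force distribution by squared-activation minimization.

Given the net joint moments, each frame solves the muscle redundancy problem

    min   sum_i a_i^2 + w_res * sum_j r_j^2
    s.t.  sum_i a_i * Fhat_i * R_ij + r_j = M_j      (each constrained coord j)
          0 <= a_i <= 1

where ``Fhat_i = f_L,i * F_max,i * cos(pennation_i)`` is the force available
from muscle ``i`` at its current length (rigid tendon; force-velocity
omitted for these slow movements), ``R_ij`` is the tendon-excursion moment
arm ``-dL_i/dq_j``, and ``r_j`` are weakly weighted reserve moments that
guarantee feasibility; large reserve usage marks a frame infeasible.  The
problem is a bound-constrained linear least-squares system and is solved
exactly per frame.

The constrained coordinates are the five free coordinates (three shoulder,
elbow flexion, forearm rotation).  Scapulothoracic muscles act on shoulder
elevation through the scapulohumeral-rhythm coupling: perturbing elevation
moves the prescribed girdle coordinates, so their paths lengthen and they
acquire real elevation moment arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .inverse_dynamics import JointMomentTrajectory, perturbed_coordinates
from .model_registry import (
    GenericModel,
    MuscleGeometry,
    MuscleParameters,
    fk_from_array,
    path_points_world,
)
from .trajectories import PoseTrajectory

__all__ = [
    "SOSettings",
    "MuscleState",
    "ActivationSolution",
    "MuscleForceTrajectory",
    "musculotendon_geometry",
    "solve_frame_so",
    "solve_trajectory_so",
]

#: Width of the Gaussian active force-length curve (normalized fiber length).
FORCE_LENGTH_WIDTH = 0.45
#: Fiber length floor, as a fraction of optimal fiber length.
FIBER_FLOOR = 0.01


@dataclass
class SOSettings:
    force_length: bool = True  # False = ideal-force mode (f_L = 1)
    reserve_weight: float = 1000.0
    moment_arm_dq_deg: float = 0.1  # total central-difference span
    feasible_rel: float = 0.01
    feasible_abs: float = 0.1  # N m
    max_infeasible_fraction: float = 0.10
    # moment-balanced coordinates; None = all free coordinates except forearm
    # rotation, which has no pronator in the registry and is IK-regularized
    constrained_coordinates: Optional[Sequence[str]] = None

    def constrained(self, free_coordinates: Sequence[str]) -> List[str]:
        if self.constrained_coordinates is not None:
            return [c for c in free_coordinates if c in self.constrained_coordinates]
        return [c for c in free_coordinates if c != "forearm_rotation"]


@dataclass
class MuscleState:
    """Length state and moment arms of one muscle at one pose."""

    musculotendon_length: float  # m
    fiber_length: float  # m
    normalized_fiber_length: float
    f_l: float  # active force-length scale in [0, 1]
    moment_arms: Dict[str, float]  # m, tendon-excursion convention -dL/dq
    floored: bool = False  # fiber length hit the floor (L_mt < l_ts region)


def _path_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


class _PathCache:
    """Precomputed arrays to evaluate every muscle path length in one pass."""

    def __init__(self, model: GenericModel):
        flat: List[Tuple[str, Tuple[float, float, float]]] = []
        pair_a: List[int] = []
        pair_b: List[int] = []
        pair_muscle: List[int] = []
        for mi, p in enumerate(model.muscles):
            g = model.muscle_geometry(p.name)
            start = len(flat)
            flat.extend(g.path_points)
            for i in range(start, len(flat) - 1):
                pair_a.append(i)
                pair_b.append(i + 1)
                pair_muscle.append(mi)
        self.n_muscles = len(model.muscles)
        self.pair_a = np.asarray(pair_a)
        self.pair_b = np.asarray(pair_b)
        self.pair_muscle = np.asarray(pair_muscle)
        self.groups = []
        for seg in model.chain.segments:
            idx = [i for i, (s, _) in enumerate(flat) if s == seg]
            if idx:
                offs = np.asarray([flat[i][1] for i in idx], dtype=float)
                self.groups.append((seg, np.asarray(idx), offs))
        self.n_points = len(flat)

    def lengths(self, poses) -> np.ndarray:
        pts = np.empty((self.n_points, 3))
        for seg, idx, offs in self.groups:
            r, p = poses[seg]
            pts[idx] = offs @ r.T + p
        d = np.linalg.norm(pts[self.pair_b] - pts[self.pair_a], axis=1)
        return np.bincount(self.pair_muscle, weights=d, minlength=self.n_muscles)


def _path_cache(model: GenericModel) -> _PathCache:
    cache = getattr(model, "_so_path_cache", None)
    if cache is None:
        cache = _PathCache(model)
        model._so_path_cache = cache
    return cache


def _force_length(lnorm: float) -> float:
    return math.exp(-(((lnorm - 1.0) / FORCE_LENGTH_WIDTH) ** 2))


def musculotendon_geometry(
    pose: Mapping[str, float],
    muscle: MuscleGeometry,
    model: GenericModel,
    rhythm_slopes: Optional[Mapping[str, float]] = None,
    settings: Optional[SOSettings] = None,
) -> MuscleState:
    """Path length, rigid-tendon fiber state and moment arms at one pose."""
    settings = settings or SOSettings()
    chain = model.chain
    cidx = {n: i for i, n in enumerate(chain.coordinate_names)}
    q = chain.q_array(pose)
    params = model.muscle(muscle.muscle_name)
    poses = fk_from_array(chain, q)
    length = _path_length(path_points_world(muscle, poses))
    half = settings.moment_arm_dq_deg / 2.0
    arms = {}
    for coord in muscle.spanned_coordinates:
        lp = _path_length(
            path_points_world(
                muscle,
                fk_from_array(
                    chain, perturbed_coordinates(q, cidx, coord, half, rhythm_slopes)
                ),
            )
        )
        lm = _path_length(
            path_points_world(
                muscle,
                fk_from_array(
                    chain, perturbed_coordinates(q, cidx, coord, -half, rhythm_slopes)
                ),
            )
        )
        arms[coord] = -(lp - lm) / math.radians(settings.moment_arm_dq_deg)
    return _muscle_state(length, params, arms, settings)


def _muscle_state(
    length: float, params: MuscleParameters, arms: Dict[str, float], settings: SOSettings
) -> MuscleState:
    cos_penn = math.cos(math.radians(params.alpha_penn))
    fiber = (length - params.l_ts) / cos_penn
    floored = fiber < FIBER_FLOOR * params.l_opt
    if floored:
        fiber = FIBER_FLOOR * params.l_opt
    lnorm = fiber / params.l_opt
    f_l = _force_length(lnorm) if settings.force_length else 1.0
    return MuscleState(
        musculotendon_length=length,
        fiber_length=fiber,
        normalized_fiber_length=lnorm,
        f_l=f_l,
        moment_arms=arms,
        floored=floored,
    )


@dataclass
class FrameSolution:
    activations: np.ndarray
    muscle_forces: np.ndarray  # N
    reserve_moments: Dict[str, float]  # N m
    objective_value: float  # sum a_i^2
    feasible: bool


@dataclass
class ActivationSolution:
    """Trajectory-level static-optimization output."""

    times: np.ndarray
    muscle_names: List[str]
    activations: np.ndarray  # (n, m)
    muscle_forces: np.ndarray  # (n, m) N
    coordinate_names: List[str]
    reserve_moments: np.ndarray  # (n, j) N m
    objective_value: np.ndarray  # (n,)
    feasible_flags: np.ndarray  # (n,) bool
    meta: dict = field(default_factory=dict)


@dataclass
class MuscleForceTrajectory:
    """Per-muscle force series plus aggregated head-group columns."""

    times: np.ndarray
    forces: Dict[str, np.ndarray]  # N; individual muscles and base-name groups
    solution: Optional[ActivationSolution] = None
    meta: dict = field(default_factory=dict)


def _bounded_activation_qp(w_mat: np.ndarray, b: np.ndarray, max_iter: int = 200):
    """Exact minimizer of ``||a||^2 + ||W a - b||^2`` subject to 0 <= a <= 1.

    Primal active-set iteration on the normal equations; the problem is
    strictly convex (Hessian ``I + W^T W``), so the KKT point is the unique
    optimum.  Returns None when the iteration cap is hit (caller falls back
    to a generic bounded solver).
    """
    m = w_mat.shape[1]
    h = np.eye(m) + w_mat.T @ w_mat
    f = w_mat.T @ b
    state = -np.ones(m, dtype=int)  # -1 at lower bound, 0 free, +1 at upper
    a = np.zeros(m)
    tol = 1e-10
    for _ in range(max_iter):
        g = f - h @ a  # negative half-gradient
        rel = ((state == -1) & (g > tol)) | ((state == 1) & (g < -tol))
        if not rel.any():
            return np.clip(a, 0.0, 1.0)
        cands = np.where(rel)[0]
        state[cands[np.argmax(np.abs(g[cands]))]] = 0
        # inner loop: equality solve on the free set, stepping to the first
        # bound hit (Lawson-Hanson with upper bounds)
        for _ in range(max_iter):
            free = state == 0
            target = np.where(state == 1, 1.0, 0.0)
            rhs = f[free]
            upper = state == 1
            if upper.any():
                rhs = rhs - h[np.ix_(free, upper)].sum(axis=1)
            target[free] = np.linalg.solve(h[np.ix_(free, free)], rhs)
            inside = (target[free] > -tol) & (target[free] < 1.0 + tol)
            if inside.all():
                a = np.clip(target, 0.0, 1.0)
                a[state == -1] = 0.0
                a[state == 1] = 1.0
                break
            # largest feasible step from a toward target over the free set
            d = target - a
            alpha = 1.0
            limiting = -1
            limit_state = 0
            for i in np.where(free)[0]:
                if d[i] < -tol and target[i] < 0.0:
                    step = (0.0 - a[i]) / d[i]
                    if step < alpha:
                        alpha, limiting, limit_state = step, i, -1
                elif d[i] > tol and target[i] > 1.0:
                    step = (1.0 - a[i]) / d[i]
                    if step < alpha:
                        alpha, limiting, limit_state = step, i, 1
            a = np.clip(a + alpha * d, 0.0, 1.0)
            if limiting >= 0:
                state[limiting] = limit_state
                a[limiting] = 0.0 if limit_state == -1 else 1.0
            else:
                break
    return None


def solve_frame_so(
    moments: Mapping[str, float],
    states: Sequence[MuscleState],
    params: Sequence[MuscleParameters],
    settings: Optional[SOSettings] = None,
) -> FrameSolution:
    """Distribute one frame's net moments over the muscles.

    Raises ``ValueError`` when a constrained coordinate is spanned by no
    muscle.  The solution is the exact optimum of the quadratic program via
    bounded linear least squares.
    """
    settings = settings or SOSettings()
    coords = list(moments)
    m = len(states)
    fhat = np.array(
        [
            s.f_l * p.f_max_iso * math.cos(math.radians(p.alpha_penn))
            for s, p in zip(states, params)
        ]
    )
    r = np.array(
        [[s.moment_arms.get(c, 0.0) for c in coords] for s in states]
    )  # (m, j)
    if not np.all(np.isfinite(r)):
        raise ValueError("moment arms must be finite")
    for j, c in enumerate(coords):
        if not np.any(r[:, j] != 0.0):
            raise ValueError(f"no muscle spans constrained coordinate {c!r}")
    mvec = np.array([moments[c] for c in coords])
    c_mat = (fhat[:, None] * r).T  # (j, m): torque capacity per unit activation
    sw = math.sqrt(settings.reserve_weight)
    a = _bounded_activation_qp(sw * c_mat, sw * mvec)
    if a is None:  # active-set fallback: generic bounded least squares
        a_mat = np.vstack([np.eye(m), sw * c_mat])
        b_vec = np.concatenate([np.zeros(m), sw * mvec])
        sol = lsq_linear(a_mat, b_vec, bounds=(0.0, 1.0), method="bvls")
        a = np.clip(sol.x, 0.0, 1.0)
    reserves = mvec - c_mat @ a
    feasible = bool(
        np.all(
            np.abs(reserves) <= settings.feasible_rel * np.abs(mvec) + settings.feasible_abs
        )
    )
    return FrameSolution(
        activations=a,
        muscle_forces=a * fhat,
        reserve_moments={c: float(rv) for c, rv in zip(coords, reserves)},
        objective_value=float(np.sum(a**2)),
        feasible=feasible,
    )


def _frame_states(
    model: GenericModel,
    q_deg: np.ndarray,
    cidx: Mapping[str, int],
    rhythm_slopes: Optional[Mapping[str, float]],
    settings: SOSettings,
) -> List[MuscleState]:
    """Length states and moment arms of all muscles with shared FK calls."""
    chain = model.chain
    free = chain.free_coordinates
    half = settings.moment_arm_dq_deg / 2.0
    cache = _path_cache(model)
    lengths0 = cache.lengths(fk_from_array(chain, q_deg))
    # perturbed lengths per free coordinate, all muscles at once
    dlen: Dict[str, np.ndarray] = {}
    for coord in free:
        lp = cache.lengths(
            fk_from_array(
                chain, perturbed_coordinates(q_deg, cidx, coord, half, rhythm_slopes)
            )
        )
        lm = cache.lengths(
            fk_from_array(
                chain, perturbed_coordinates(q_deg, cidx, coord, -half, rhythm_slopes)
            )
        )
        dlen[coord] = lp - lm
    states = []
    drad = math.radians(settings.moment_arm_dq_deg)
    for mi, muscle in enumerate(model.muscles):
        g = model.muscle_geometry(muscle.name)
        arms = {
            coord: -dlen[coord][mi] / drad
            for coord in g.spanned_coordinates
            if coord in dlen
        }
        states.append(_muscle_state(float(lengths0[mi]), muscle, arms, settings))
    return states


def solve_trajectory_so(
    pose: PoseTrajectory,
    moments: JointMomentTrajectory,
    model: GenericModel,
    settings: Optional[SOSettings] = None,
    rhythm_slopes: Optional[Mapping[str, float]] = None,
) -> MuscleForceTrajectory:
    """Frame-wise static optimization over a trajectory.

    ``pose`` and ``moments`` must share a time base.  The output carries one
    force column per muscle plus aggregated base-name columns (head sums)
    matching the report rows; the trial is flagged in ``meta['so_flagged']``
    when more than ``max_infeasible_fraction`` of frames are infeasible.
    """
    settings = settings or SOSettings()
    if len(pose.times) != len(moments.times) or np.any(
        np.abs(pose.times - moments.times) > 1e-9
    ):
        raise ValueError("pose and moments must share a time base")
    chain = model.chain
    names = chain.coordinate_names
    cidx = {n: i for i, n in enumerate(names)}
    coords = [c for c in settings.constrained(chain.free_coordinates) if c in moments.moments]
    q = pose.matrix(names)
    mus_params = list(model.muscles)
    n = pose.n_frames
    m = len(mus_params)
    activations = np.empty((n, m))
    forces = np.empty((n, m))
    reserves = np.empty((n, len(coords)))
    objective = np.empty(n)
    feasible = np.empty(n, dtype=bool)
    mom = moments.matrix(coords)
    for t in range(n):
        states = _frame_states(model, q[t], cidx, rhythm_slopes, settings)
        frame = solve_frame_so(
            {c: mom[t, j] for j, c in enumerate(coords)}, states, mus_params, settings
        )
        activations[t] = frame.activations
        forces[t] = frame.muscle_forces
        reserves[t] = [frame.reserve_moments[c] for c in coords]
        objective[t] = frame.objective_value
        feasible[t] = frame.feasible
    force_cols: Dict[str, np.ndarray] = {
        p.name: forces[:, i] for i, p in enumerate(mus_params)
    }
    groups: Dict[str, List[int]] = {}
    for i, p in enumerate(mus_params):
        groups.setdefault(p.base_name, []).append(i)
    for base, idxs in groups.items():
        if base not in force_cols:
            force_cols[base] = forces[:, idxs].sum(axis=1)
    infeasible_frac = float(np.mean(~feasible)) if n else 0.0
    meta = {
        **pose.meta,
        "so_flagged": infeasible_frac > settings.max_infeasible_fraction,
        "so_infeasible_fraction": infeasible_frac,
        "so_force_length": settings.force_length,
    }
    solution = ActivationSolution(
        times=pose.times.copy(),
        muscle_names=[p.name for p in mus_params],
        activations=activations,
        muscle_forces=forces,
        coordinate_names=coords,
        reserve_moments=reserves,
        objective_value=objective,
        feasible_flags=feasible,
        meta=meta,
    )
    return MuscleForceTrajectory(
        times=pose.times.copy(), forces=force_cols, solution=solution, meta=meta
    )
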