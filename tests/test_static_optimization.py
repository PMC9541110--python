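"""Muscle redundancy solver: moment arms, force-length state, QP optimality."""

import math

import numpy as np
import pytest

from camforce.inverse_dynamics import compute_net_moments, make_external_load
from camforce.model_registry import MuscleGeometry, MuscleParameters
from camforce.static_optimization import (
    MuscleState,
    SOSettings,
    musculotendon_geometry,
    solve_frame_so,
    solve_trajectory_so,
)
from camforce.synthetic_data import generate_ground_truth


def _state(arms, f_l=1.0):
    return MuscleState(
        musculotendon_length=0.2,
        fiber_length=0.1,
        normalized_fiber_length=1.0,
        f_l=f_l,
        moment_arms=arms,
    )


def _params(name, fmax, penn=0.0):
    return MuscleParameters(name, "", fmax, 0.1, 0.1, penn, "test")


def _ideal():
    return SOSettings(force_length=False)


# ---------------------------------------------------------------------------
# musculotendon geometry


def test_two_point_chord_moment_arm_matches_analytic(model):
    """Chord across a hinge: arm = -dL/dq equals the analytic derivative.

    Both endpoints sit at radius r from the elbow axis; the chord length is
    L = 2 r sin(delta/2) with separation delta = delta0 - q, so the moment
    arm is -dL/dq = r cos((delta0 - q)/2).
    """
    r = 0.05
    # humerus point at +Z from the elbow center, forearm point at -Y, both
    # radius r: initial separation 90 degrees
    geo = MuscleGeometry(
        muscle_name="Teres minor",  # parameters only; geometry is the probe
        path_points=(("humerus", (0.0, -0.30, r)), ("forearm", (0.0, -r, 0.0))),
        spanned_coordinates=("elbow_flexion",),
    )
    for q in [10.0, 30.0, 60.0]:
        pose = {c: 0.0 for c in model.chain.coordinate_names}
        pose["elbow_flexion"] = q
        st = musculotendon_geometry(pose, geo, model)
        analytic = r * math.cos(math.radians((90.0 - q) / 2.0))
        assert st.moment_arms["elbow_flexion"] == pytest.approx(analytic, rel=0.01)


def test_force_length_peak_and_ideal_mode(model, neutral):
    geo = model.muscle_geometry("Teres minor")
    st = musculotendon_geometry(neutral, geo, model)
    # f_L is the Gaussian of normalized fiber length, 1 exactly at optimum
    expected = math.exp(-(((st.normalized_fiber_length - 1.0) / 0.45) ** 2))
    assert st.f_l == pytest.approx(expected, rel=1e-12)
    st_ideal = musculotendon_geometry(
        neutral, geo, model, settings=SOSettings(force_length=False)
    )
    assert st_ideal.f_l == 1.0


def test_fiber_length_floor_flagged(model, neutral):
    # a two-point path much shorter than the tendon slack length
    geo = MuscleGeometry(
        muscle_name="Biceps long",  # l_ts = 0.257 m
        path_points=(("humerus", (0.0, -0.28, 0.01)), ("forearm", (0.0, -0.01, 0.01))),
        spanned_coordinates=("elbow_flexion",),
    )
    st = musculotendon_geometry(neutral, geo, model)
    assert st.floored
    assert st.fiber_length == pytest.approx(0.01 * model.muscle("Biceps long").l_opt)


# ---------------------------------------------------------------------------
# frame solver


def test_two_muscle_equal_capacity_split():
    """Equal torque capacities share the load equally (Lagrange closed form)."""
    states = [_state({"c": 0.02}), _state({"c": 0.01})]
    params = [_params("a", 100.0), _params("b", 200.0)]
    sol = solve_frame_so({"c": 2.0}, states, params, _ideal())
    assert np.allclose(sol.activations, [0.5, 0.5], atol=0.005)
    assert np.allclose(sol.muscle_forces, [50.0, 100.0], atol=0.5)
    assert sol.feasible


def test_zero_moment_zero_activation():
    states = [_state({"c": 0.02}), _state({"c": -0.01})]
    params = [_params("a", 100.0), _params("b", 200.0)]
    sol = solve_frame_so({"c": 0.0}, states, params, _ideal())
    assert np.allclose(sol.activations, 0.0, atol=1e-9)
    assert sol.objective_value == pytest.approx(0.0, abs=1e-12)


def test_saturated_muscle_uses_reserve():
    states = [_state({"c": 0.01})]
    params = [_params("a", 100.0)]  # capacity 1 N m < demand 2 N m
    sol = solve_frame_so({"c": 2.0}, states, params, _ideal())
    assert sol.activations[0] == pytest.approx(1.0, abs=1e-6)
    assert sol.reserve_moments["c"] == pytest.approx(1.0, abs=1e-3)
    assert not sol.feasible


def test_unspanned_coordinate_rejected():
    states = [_state({"c": 0.02})]
    params = [_params("a", 100.0)]
    with pytest.raises(ValueError, match="spans"):
        solve_frame_so({"c": 1.0, "d": 1.0}, states, params, _ideal())


def test_kkt_proportionality_two_muscles():
    """Unclamped optimum: activation proportional to torque capacity."""
    rng = np.random.default_rng(51)
    for _ in range(20):
        c1, c2 = rng.uniform(0.5, 3.0, 2)
        m_demand = rng.uniform(0.05, 0.3) * (c1 + c2)
        states = [_state({"c": 1.0}), _state({"c": 1.0})]
        params = [_params("a", c1), _params("b", c2)]
        sol = solve_frame_so({"c": m_demand}, states, params, _ideal())
        if sol.activations.max() < 0.99:
            assert sol.activations[0] * c2 == pytest.approx(
                sol.activations[1] * c1, rel=1e-6
            )


def grid_oracle_2d(fhat, arms, demands, w=1000.0, step=0.00025):
    """Exhaustive fine-grid search for two-muscle instances.

    The step is finer than the 0.005 comparison band because grid
    quantization of the compensating activation leaves several steps of
    slack along the soft-constraint valley.  Evaluated in row blocks to
    bound memory.
    """
    cap = fhat[:, None] * arms  # (2, j)
    axis = np.arange(0.0, 1.0 + step / 2, step)
    best_val = np.inf
    best = None
    for a1 in axis:
        res = demands[None, :] - (a1 * cap[0])[None, :] - np.outer(axis, cap[1])
        vals = a1**2 + axis**2 + w * np.sum(res**2, axis=-1)
        k = int(np.argmin(vals))
        if vals[k] < best_val:
            best_val = float(vals[k])
            best = np.array([a1, axis[k]])
    return best


def enumeration_oracle(fhat, arms, demands, w=1000.0):
    """Exact optimum by enumerating every {lower, free, upper} bound pattern.

    The objective ||a||^2 + w ||M - C a||^2 is strictly convex, so the unique
    optimum is the best KKT-feasible stationary point over all 3^m patterns.
    """
    import itertools

    m = len(fhat)
    cap = (fhat[:, None] * arms)  # (m, j)
    h = np.eye(m) + w * (cap @ cap.T)
    f = w * (cap @ demands)

    def objective(a):
        r = demands - a @ cap
        return float(a @ a + w * (r @ r))

    best, best_val = None, np.inf
    for pattern in itertools.product((-1, 0, 1), repeat=m):
        pattern = np.asarray(pattern)
        free = pattern == 0
        a = np.where(pattern == 1, 1.0, 0.0).astype(float)
        if free.any():
            rhs = f[free] - h[np.ix_(free, pattern == 1)].sum(axis=1)
            try:
                a[free] = np.linalg.solve(h[np.ix_(free, free)], rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(a[free] < -1e-12) or np.any(a[free] > 1 + 1e-12):
                continue
        g = h @ a - f  # half-gradient
        if np.any(g[pattern == -1] < -1e-8) or np.any(g[pattern == 1] > 1e-8):
            continue
        val = objective(np.clip(a, 0, 1))
        if val < best_val:
            best, best_val = np.clip(a, 0, 1), val
    return best


def test_frame_solutions_match_independent_oracles():
    """50 random small instances agree with brute-force optimization.

    Two-muscle instances are checked against an exhaustive 0.001-step grid;
    three-muscle instances against exact enumeration of all bound patterns
    (a full 0.001 grid over three activations is computationally out of
    reach, and coarse-to-fine grids are unreliable in the soft-constraint
    valley).
    """
    rng = np.random.default_rng(52)
    worst = 0.0
    n_two = n_three = 0
    for _ in range(50):
        m = int(rng.integers(2, 4))
        j = int(rng.integers(1, 3))
        fhat = rng.uniform(50.0, 500.0, m)
        arms = rng.uniform(-0.04, 0.04, (m, j))
        demands = rng.uniform(-2.0, 2.0, j)
        coords = [f"c{k}" for k in range(j)]
        states = [
            _state({c: arms[i, k] for k, c in enumerate(coords)}) for i in range(m)
        ]
        params = [_params(f"m{i}", fhat[i]) for i in range(m)]
        sol = solve_frame_so(dict(zip(coords, demands)), states, params, _ideal())
        enum = enumeration_oracle(fhat, arms, demands)
        assert enum is not None
        assert np.max(np.abs(sol.activations - enum)) <= 1e-6
        if m == 2:
            ref = grid_oracle_2d(fhat, arms, demands)
            n_two += 1
        else:
            ref = enum
            n_three += 1
        worst = max(worst, float(np.max(np.abs(sol.activations - ref))))
    assert n_two > 5 and n_three > 5
    assert worst <= 0.005


def test_objective_monotone_in_moment_scale():
    rng = np.random.default_rng(53)
    fhat = rng.uniform(100.0, 400.0, 4)
    arms = rng.uniform(-0.03, 0.03, (4, 2))
    demands = np.array([1.5, -0.8])
    states = [_state({"c0": arms[i, 0], "c1": arms[i, 1]}) for i in range(4)]
    params = [_params(f"m{i}", fhat[i]) for i in range(4)]
    prev = np.inf
    for k in [1.0, 0.7, 0.4, 0.1]:
        sol = solve_frame_so({"c0": k * demands[0], "c1": k * demands[1]}, states, params, _ideal())
        assert sol.objective_value <= prev + 1e-12
        prev = sol.objective_value


# ---------------------------------------------------------------------------
# trajectory solver


def test_moment_reproduction_on_feasible_frames(model, regression, fly_profile):
    truth = generate_ground_truth(fly_profile, model, seed=61, rate=25.0)
    load = make_external_load(3.0)
    moments = compute_net_moments(truth, model, load, rhythm_slopes=regression.rhythm_slopes)
    settings = SOSettings()
    mft = solve_trajectory_so(truth, moments, model, settings, rhythm_slopes=regression.rhythm_slopes)
    sol = mft.solution
    for t in range(sol.activations.shape[0]):
        if not sol.feasible_flags[t]:
            continue
        for j, c in enumerate(sol.coordinate_names):
            demand = moments.moments[c][t]
            tol = settings.feasible_rel * abs(demand) + settings.feasible_abs
            assert abs(sol.reserve_moments[t, j]) <= tol + 1e-9


def test_zero_load_neutral_trial_near_zero_forces(model, regression):
    import camforce.trajectories as tj

    n = 51
    times = np.arange(n) / 50.0
    neutral = tj.PoseTrajectory(
        times=times,
        coordinates={c: np.zeros(n) for c in model.chain.coordinate_names},
        meta={"rate": 50.0},
    )
    moments = compute_net_moments(
        neutral, model, make_external_load(0.0), rhythm_slopes=regression.rhythm_slopes
    )
    mft = solve_trajectory_so(neutral, moments, model, rhythm_slopes=regression.rhythm_slopes)
    assert np.max(mft.solution.muscle_forces) < 50.0
    assert np.max(mft.solution.activations) < 0.05


def test_biceps_track_elbow_moment(model, regression, curl_profile):
    """The biceps' elbow-moment contribution tracks the net moment demand.

    The comparison is in moment space (force times angle-dependent moment
    arm): the biceps carry essentially the whole elbow demand, so their
    contribution must peak with it.
    """
    truth = generate_ground_truth(curl_profile, model, seed=62, rate=25.0)
    load = make_external_load(5.0)
    moments = compute_net_moments(truth, model, load, rhythm_slopes=regression.rhythm_slopes)
    mft = solve_trajectory_so(truth, moments, model, rhythm_slopes=regression.rhythm_slopes)
    sol = mft.solution
    names = sol.muscle_names
    contribution = np.zeros(len(sol.times))
    cidx = {n: i for i, n in enumerate(model.chain.coordinate_names)}
    from camforce.static_optimization import _frame_states, SOSettings

    q = truth.matrix(model.chain.coordinate_names)
    settings = SOSettings()
    for t in range(len(sol.times)):
        states = _frame_states(model, q[t], cidx, regression.rhythm_slopes, settings)
        for i, nm in enumerate(names):
            if nm.startswith("Biceps"):
                contribution[t] += sol.muscle_forces[t, i] * states[i].moment_arms.get(
                    "elbow_flexion", 0.0
                )
    t_contrib = sol.times[int(np.argmax(contribution))]
    t_moment = moments.times[int(np.argmax(moments.moments["elbow_flexion"]))]
    assert abs(t_contrib - t_moment) <= 0.1
    # and the summed biceps force itself is large whenever the demand is
    demand = moments.moments["elbow_flexion"]
    assert np.corrcoef(contribution, demand)[0, 1] > 0.99


def test_trajectory_determinism(model, regression, curl_profile):
    truth = generate_ground_truth(curl_profile, model, seed=63, rate=25.0)
    load = make_external_load(5.0)
    moments = compute_net_moments(truth, model, load, rhythm_slopes=regression.rhythm_slopes)
    a = solve_trajectory_so(truth, moments, model, rhythm_slopes=regression.rhythm_slopes)
    b = solve_trajectory_so(truth, moments, model, rhythm_slopes=regression.rhythm_slopes)
    for key in a.forces:
        assert np.array_equal(a.forces[key], b.forces[key])


def test_aggregated_head_columns_sum(model, regression, curl_profile):
    truth = generate_ground_truth(curl_profile, model, seed=64, rate=10.0)
    load = make_external_load(5.0)
    moments = compute_net_moments(truth, model, load, rhythm_slopes=regression.rhythm_slopes)
    mft = solve_trajectory_so(truth, moments, model, rhythm_slopes=regression.rhythm_slopes)
    assert np.allclose(
        mft.forces["Biceps"], mft.forces["Biceps long"] + mft.forces["Biceps brevis"]
    )
    assert np.allclose(
        mft.forces["Infraspinatus"],
        mft.forces["Infraspinatus superior"] + mft.forces["Infraspinatus inferior"],
    )
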