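"""Joint-center estimation, quality control, scaling, and the girdle rhythm."""

import numpy as np
import pytest

from camforce.model_registry import chain_forward_kinematics
from camforce.preprocess import (
    RegressionCoefficients,
    compute_scales,
    default_regression,
    estimate_joint_centers,
    prescribe_scapula_clavicle,
    qc_camera_trial,
    qc_marker_trial,
)
from camforce.synthetic_data import NoiseModel, render_camera_stream, render_marker_stream
from camforce.trajectories import MARKER_LABELS, PoseTrajectory, TrajectorySet


def _mini_marker_stream(**positions):
    """Two-frame marker stream with the named labels at constant positions."""
    labels = list(positions)
    times = np.array([0.0, 0.01])
    points = {lab: np.tile(np.asarray(p, float), (2, 1)) for lab, p in positions.items()}
    return TrajectorySet(labels=labels, times=times, points=points, rate=100.0,
                         stream_kind="marker")


def _camera_stream(shoulder, elbow, wrist, n=10, rate=30.0):
    times = np.arange(n) / rate
    pts = {
        "Mid spine": np.tile([0.0, 0.1, -0.08], (n, 1)),
        "Mid thorax": np.tile([0.0, 0.0, 0.0], (n, 1)),
        "Shoulder joint center": np.tile(shoulder, (n, 1)),
        "Elbow joint center": np.tile(elbow, (n, 1)),
        "Wrist joint center": np.tile(wrist, (n, 1)),
    }
    return TrajectorySet(labels=list(pts), times=times, points=pts, rate=rate,
                         stream_kind="camera")


def test_midpoint_centers_exact(regression):
    stream = _mini_marker_stream(
        **{
            "Acromion": (0.2, 0.2, 0.0),
            "Epicondylus Medialis": (0.0, 0.0, 0.0),
            "Epicondylus Lateralis": (0.06, 0.0, 0.0),
            "Head of the Ulna": (1.0, 1.0, 1.0),
            "Styloid processes of radius": (1.0, 1.0, 0.0),
        }
    )
    aug = estimate_joint_centers(stream, regression)
    assert np.array_equal(aug.points["Elbow joint center"][0], [0.03, 0.0, 0.0])
    assert np.array_equal(aug.points["Wrist joint center"][0], [1.0, 1.0, 0.5])
    assert np.allclose(
        aug.points["Shoulder joint center"][0],
        np.array([0.2, 0.2, 0.0]) + regression.shoulder_offset,
    )


def test_centers_match_chain_joints_zero_noise(model, regression, fly_truth_100hz):
    """Estimated centers land on the chain's joint centers (oracle: FK)."""
    stream = render_marker_stream(fly_truth_100hz, model, NoiseModel.zero(seed=1))
    aug = estimate_joint_centers(stream, regression)
    for i in [0, stream.n_frames // 2, stream.n_frames - 1]:
        poses = chain_forward_kinematics(model.chain, fly_truth_100hz.frame(i))
        assert np.allclose(aug.points["Shoulder joint center"][i], poses["humerus"][1], atol=1e-6)
        assert np.allclose(aug.points["Elbow joint center"][i], poses["forearm"][1], atol=1e-6)
        assert np.allclose(aug.points["Wrist joint center"][i], poses["hand"][1], atol=1e-6)


def test_center_estimation_requires_landmarks(regression):
    stream = _mini_marker_stream(**{"Acromion": (0, 0, 0)})
    with pytest.raises(ValueError, match="Epicondylus"):
        estimate_joint_centers(stream, regression)
    # present label but all-missing is also a hard error
    stream2 = _mini_marker_stream(
        **{
            "Acromion": (0.2, 0.2, 0.0),
            "Epicondylus Medialis": (0.0, 0.0, 0.0),
            "Epicondylus Lateralis": (0.06, 0.0, 0.0),
            "Head of the Ulna": (1.0, 1.0, 1.0),
            "Styloid processes of radius": (1.0, 1.0, 0.0),
        }
    )
    stream2.points["Epicondylus Medialis"][:] = np.nan
    with pytest.raises(ValueError, match="missing on all frames"):
        estimate_joint_centers(stream2, regression)


def test_qc_marker_complete_included(model, curl_truth_100hz):
    stream = render_marker_stream(curl_truth_100hz, model, NoiseModel.zero(seed=2))
    rep = qc_marker_trial(stream)
    assert rep.included and rep.reason == "ok"


def test_qc_marker_segment_below_three_markers(model, curl_truth_100hz):
    stream = render_marker_stream(curl_truth_100hz, model, NoiseModel.zero(seed=2))
    for lab in ("Epicondylus Medialis", "Epicondylus Lateralis", "Lower arm"):
        stream.points[lab][:] = np.nan
    rep = qc_marker_trial(stream)
    assert not rep.included
    assert rep.reason == "too_many_missing_markers"
    assert "upper_arm" in rep.offending or "lower_arm" in rep.offending


def test_qc_marker_sparse_dropout_tolerated(model, curl_truth_100hz):
    stream = render_marker_stream(curl_truth_100hz, model, NoiseModel.zero(seed=2))
    n = stream.n_frames
    drop = np.arange(0, n // 100)  # 1% of frames
    stream.points["Acromion"][drop] = np.nan
    assert qc_marker_trial(stream).included


def test_qc_camera_zero_noise_included(model, curl_truth_100hz):
    stream = render_camera_stream(curl_truth_100hz, model, NoiseModel.zero(seed=3))
    assert qc_camera_trial(stream).included


def test_qc_camera_collapsed_skeleton_excluded(model, curl_truth_100hz):
    stream = render_camera_stream(curl_truth_100hz, model, NoiseModel(failure_prob=1.0, seed=3))
    rep = qc_camera_trial(stream)
    assert not rep.included and rep.reason == "unrealistic_pose"


def test_qc_camera_boundary_length_included():
    stream = _camera_stream([0.0, 0.0, 0.0], [0.0, -0.15, 0.0], [0.0, -0.41, 0.0])
    assert qc_camera_trial(stream).included  # exactly 0.15 m passes


def test_qc_camera_teleporting_centers_excluded():
    stream = _camera_stream([0.0, 0.0, 0.0], [0.0, -0.3, 0.0], [0.0, -0.56, 0.0])
    rng = np.random.default_rng(0)
    for lab in stream.labels:
        stream.points[lab] += rng.normal(0, 2.0, stream.points[lab].shape)
    rep = qc_camera_trial(stream)
    assert not rep.included and rep.reason == "unrealistic_pose"


def test_scales_identity_and_ratio(model, regression):
    zero = NoiseModel.zero(seed=4)
    n = 61
    times = np.arange(n) / 100.0
    neutral = PoseTrajectory(
        times=times,
        coordinates={c: np.zeros(n) for c in model.chain.coordinate_names},
        meta={"rate": 100.0},
    )
    marker = estimate_joint_centers(render_marker_stream(neutral, model, zero), regression)
    camera = render_camera_stream(neutral, model, zero)
    ms = compute_scales(marker, model)
    cs = compute_scales(camera, model)
    for seg, f in ms.factors.items():
        assert np.allclose(f, 1.0, atol=1e-9), seg
    for seg, f in cs.factors.items():
        assert np.allclose(f, 1.0, atol=1e-6), seg
    # camera thorax factors are uniform by construction
    assert cs.factors["thorax"][0] == cs.factors["thorax"][1] == cs.factors["thorax"][2]
    assert ms.method == "per_axis" and cs.method == "uniform"
    # homogeneity: doubling all measured coordinates doubles every factor
    for lab in marker.labels:
        marker.points[lab] *= 2.0
    ms2 = compute_scales(marker, model)
    for seg in ms.factors:
        assert np.allclose(ms2.factors[seg], 2.0 * ms.factors[seg], atol=1e-9)


def test_scales_degenerate_pair_rejected(model, regression):
    zero = NoiseModel.zero(seed=4)
    n = 11
    times = np.arange(n) / 100.0
    neutral = PoseTrajectory(
        times=times,
        coordinates={c: np.zeros(n) for c in model.chain.coordinate_names},
        meta={"rate": 100.0},
    )
    marker = render_marker_stream(neutral, model, zero)
    pairs = {"thorax": [("Incisura Jugularis", "Incisura Jugularis", ("x", "y", "z"))]}
    with pytest.raises(ValueError, match="degenerate"):
        compute_scales(marker, model, pairs=pairs)


def test_scales_recover_longer_humerus_under_noise(model, regression):
    """Camera scaling finds a +10% humerus within 1% on average."""
    subject = model.scaled({"humerus": (1.1, 1.1, 1.1)})
    n = 151  # 5 s at 30 Hz
    times = np.arange(n) / 30.0
    neutral = PoseTrajectory(
        times=times,
        coordinates={c: np.zeros(n) for c in subject.chain.coordinate_names},
        meta={"rate": 30.0},
    )
    factors = []
    for seed in range(100):
        noise = NoiseModel(seed=seed)  # default camera noise
        cam = render_camera_stream(neutral, subject, noise, rate=30.0)
        cs = compute_scales(cam, model)
        factors.append(cs.factors["humerus"][1])
    assert 1.09 <= float(np.mean(factors)) <= 1.11


def test_qc_determinism(model, curl_truth_100hz):
    stream = render_marker_stream(curl_truth_100hz, model, NoiseModel(seed=5))
    r1 = qc_marker_trial(stream)
    r2 = qc_marker_trial(stream)
    assert (r1.included, r1.reason, r1.offending) == (r2.included, r2.reason, r2.offending)


def test_rhythm_affine_prescription():
    n = 3
    times = np.arange(n) / 10.0
    pose = PoseTrajectory(
        times=times,
        coordinates={"shoulder_elevation": np.array([0.0, 45.0, 90.0])},
    )
    coeffs = RegressionCoefficients(
        rhythm_slopes={"scap_upward_rotation": 0.5},
        rhythm_intercepts={"scap_upward_rotation": 3.0, "clav_elevation": 2.0},
        provenance="test stand-in",
    )
    out = prescribe_scapula_clavicle(pose, coeffs)
    assert np.allclose(out.coordinates["scap_upward_rotation"], [3.0, 25.5, 48.0])
    # intercept-only coordinate is constant; unspecified ones are zero
    assert np.allclose(out.coordinates["clav_elevation"], 2.0)
    assert np.allclose(out.coordinates["scap_tilt"], 0.0)
    zeroed = RegressionCoefficients(provenance="zeros")
    out0 = prescribe_scapula_clavicle(pose, zeroed)
    assert np.allclose(out0.coordinates["scap_protraction"], 0.0)


def test_regression_requires_provenance():
    with pytest.raises(ValueError, match="provenance"):
        RegressionCoefficients(provenance="")
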