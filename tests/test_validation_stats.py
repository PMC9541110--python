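"""Synchronization, resampling, filtering, RMSD/correlation, Bland-Altman."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from camforce.static_optimization import MuscleForceTrajectory
from camforce.trajectories import PoseTrajectory
from camforce.validation_stats import (
    AnalysisConfig,
    aggregate,
    bland_altman,
    categorize_r,
    filter_forces,
    pct_bw_to_newton,
    pct_fmax,
    resample_to_reference,
    synchronize_pair,
    trial_statistics,
)


@pytest.fixture()
def cfg():
    return AnalysisConfig()


# ---------------------------------------------------------------------------
# resampling


def test_resample_constant_series(cfg):
    times = np.arange(10) / 30.0
    t, out = resample_to_reference(times, np.full(10, 7.5), cfg)
    assert np.allclose(out, 7.5, atol=1e-12)


def test_resample_grid_arithmetic(cfg):
    """A 2 s window: 61 samples at 30 Hz map to 801 samples at 400 Hz."""
    times = np.arange(61) / 30.0
    t, out = resample_to_reference(times, np.sin(times), cfg)
    assert len(t) == 801
    assert t[0] == times[0] and t[-1] == pytest.approx(times[-1], abs=1e-12)
    assert out[0] == math.sin(times[0]) and out[-1] == math.sin(times[-1])


def test_resample_sinusoid_accuracy(cfg):
    times = np.arange(61) / 30.0
    values = np.sin(2 * np.pi * 1.0 * times)
    t, out = resample_to_reference(times, values, cfg)
    exact = np.sin(2 * np.pi * 1.0 * t)
    assert np.max(np.abs(out - exact)) < 0.01  # < 1% of unit amplitude


def test_resample_input_validation(cfg):
    with pytest.raises(ValueError, match="4 samples"):
        resample_to_reference(np.array([0.0, 0.1]), np.array([1.0, 2.0]), cfg)
    bad = np.array([0.0, 0.2, 0.1, 0.3])
    with pytest.raises(ValueError, match="increasing"):
        resample_to_reference(bad, np.ones(4), cfg)


# ---------------------------------------------------------------------------
# filtering


def test_filter_dc_gain_unity(cfg):
    out = filter_forces(np.full(400, 100.0), 400.0, cfg)
    assert np.max(np.abs(out - 100.0)) <= 1e-9


def _attenuation(freq, cfg, rate=400.0, duration=5.0):
    t = np.arange(int(duration * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)
    y = filter_forces(x, rate, cfg)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    return 1.0 - np.max(np.abs(y[mid]))


def test_filter_passband_attenuation(cfg):
    # two zero-phase passes of a 2nd-order 4 Hz Butterworth at 1 Hz:
    # |H|^2 = (1 + (1/4)^4)^-1 ~ 0.996, attenuation well under 5%
    assert _attenuation(1.0, cfg) < 0.05


def test_filter_stopband_attenuation(cfg):
    assert _attenuation(50.0, cfg) > 0.99


def test_filter_short_series_rejected(cfg):
    with pytest.raises(ValueError, match="warm-up"):
        filter_forces(np.ones(5), 400.0, cfg)


# ---------------------------------------------------------------------------
# trial statistics


def test_identical_windows(cfg):
    w = np.sin(np.linspace(0, 3, 50)) * 10
    comp = trial_statistics(w, w, fmax_group=100.0, muscle="x")
    assert comp.rmsd_N == 0.0
    assert comp.pearson_r == pytest.approx(1.0)
    constant = np.full(50, 5.0)
    comp2 = trial_statistics(constant, constant, fmax_group=100.0)
    assert comp2.rmsd_N == 0.0
    assert math.isnan(comp2.pearson_r)  # zero-variance rule


def test_two_frame_rmsd_hand_computed(cfg):
    comp = trial_statistics(np.array([3.0, 4.0]), np.array([0.0, 0.0]), 100.0)
    assert comp.rmsd_N == pytest.approx(math.sqrt(12.5))


def test_pct_fmax_printed_precision():
    # 6.2 N against a 1324.4 N head group prints as 0.5%
    assert round(pct_fmax(6.2, 1324.4), 1) == 0.5


def test_rmsd_symmetry_and_identity(cfg):
    rng = np.random.default_rng(71)
    a = rng.normal(0, 10, 100)
    b = rng.normal(0, 10, 100)
    assert trial_statistics(a, b, 100.0).rmsd_N == pytest.approx(
        trial_statistics(b, a, 100.0).rmsd_N
    )
    assert trial_statistics(a, a, 100.0).rmsd_N == 0.0


@hyp_settings(derandomize=True, max_examples=30)
@given(
    scale=st.floats(0.1, 50.0),
    offset=st.floats(-100.0, 100.0),
    flip=st.booleans(),
)
def test_pearson_r_affine_invariance(scale, offset, flip):
    rng = np.random.default_rng(72)
    a = rng.normal(0, 5, 80)
    b = a + rng.normal(0, 2, 80)
    base = trial_statistics(b, a, 100.0).pearson_r
    slope = -scale if flip else scale
    transformed = trial_statistics(slope * b + offset, a, 100.0).pearson_r
    assert abs(abs(transformed) - abs(base)) < 1e-9


@pytest.mark.parametrize(
    "r, category",
    [
        (0.92, "excellent"),
        (0.90, "strong"),
        (0.72, "strong"),
        (0.50, "moderate"),
        (0.35, "weak"),
        (0.31, "weak"),
        (-0.20, "weak"),
        (-0.95, "excellent"),
        (float("nan"), "undefined"),
    ],
)
def test_r_categories(r, category):
    assert categorize_r(r) == category


def test_pct_bw_conversion():
    assert round(pct_bw_to_newton(5.45, 80.0)) == 43
    assert round(pct_bw_to_newton(2.88, 80.0)) == 23


# ---------------------------------------------------------------------------
# aggregation


def test_single_subject_single_trial_aggregation():
    comp = trial_statistics(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.5, 2.0]), 500.0, "M")
    report = aggregate([("S1", "lateral_fly", comp)])
    row = report.rows[0]
    assert row.rmsd_n_mean == pytest.approx(comp.rmsd_N)
    assert row.rmsd_n_sd == 0.0
    assert row.n_subjects == 1


def test_between_subject_sd():
    rng = np.random.default_rng(73)
    trials = []
    for s, bias in [("S1", 0.0), ("S2", 5.0)]:
        for _ in range(3):
            ref = rng.normal(0, 10, 50)
            test = ref + bias + rng.normal(0, 0.1, 50)
            trials.append((s, "biceps_curl", trial_statistics(test, ref, 500.0, "M")))
    report = aggregate(trials)
    row = report.rows[0]
    assert row.n_subjects == 2
    assert row.rmsd_n_sd > 1.0  # subjects differ systematically


def test_missing_r_excluded_but_counted():
    flat = trial_statistics(np.full(10, 2.0), np.full(10, 2.0), 100.0, "M")
    varying = trial_statistics(
        np.sin(np.arange(10.0)), np.sin(np.arange(10.0)) + 0.01, 100.0, "M"
    )
    report = aggregate([("S1", "x", flat), ("S1", "x", varying)])
    row = report.rows[0]
    assert row.n_r_missing == 1
    assert row.r_mean == pytest.approx(varying.pearson_r)


# ---------------------------------------------------------------------------
# Bland-Altman


def test_bland_altman_identical_lists(cfg):
    ba = bland_altman([10.0, 20.0, 30.0], [10.0, 20.0, 30.0], cfg)
    assert ba.bias == 0.0 and ba.sd == 0.0
    assert ba.loa == (0.0, 0.0)


def test_bland_altman_symmetric_differences(cfg):
    ba = bland_altman([11.0, 19.0], [10.0, 20.0], cfg)
    assert ba.bias == 0.0
    assert ba.sd == pytest.approx(math.sqrt(2.0))  # sample SD convention (n-1)
    assert ba.loa[1] == pytest.approx(1.96 * math.sqrt(2.0))


def test_bland_altman_constant_offset(cfg):
    ba = bland_altman([15.0, 25.0, 35.0], [10.0, 20.0, 30.0], cfg,
                      subjects=["S1", "S1", "S2"])
    assert ba.bias == pytest.approx(5.0)
    assert ba.sd == 0.0
    assert ba.per_subject_bias == {"S1": 5.0, "S2": 5.0}


def test_bland_altman_length_mismatch(cfg):
    with pytest.raises(ValueError, match="equal length"):
        bland_altman([1.0, 2.0], [1.0], cfg)


def test_bland_altman_plot_writes_file(cfg, tmp_path):
    from camforce.validation_stats import bland_altman_plot

    ba = bland_altman([12.0, 18.0, 30.0], [10.0, 20.0, 28.0], cfg)
    out = tmp_path / "ba.png"
    bland_altman_plot(ba, out, title="prime mover")
    assert out.exists() and out.stat().st_size > 0


# ---------------------------------------------------------------------------
# synchronization


def _force_pose_pair(rate, n_reps=2, rep=2.5, lead=1.2, delay=0.0, rng_seed=0):
    total = 2 * lead + n_reps * rep
    n = int(total * rate) + 1
    t = np.arange(n) / rate
    angle = np.full(n, 15.0)
    force = np.zeros(n)
    for k in range(n_reps):
        t0 = lead + k * rep + delay
        mask = (t >= t0) & (t < t0 + rep)
        phase = (t[mask] - t0) / rep
        angle[mask] = 15.0 + 75.0 * 0.5 * (1 - np.cos(2 * np.pi * phase))
        force[mask] = 100.0 * 0.5 * (1 - np.cos(2 * np.pi * phase))
    pose = PoseTrajectory(times=t, coordinates={"shoulder_elevation": angle})
    forces = MuscleForceTrajectory(times=t, forces={"Deltoideus middle": force})
    return forces, pose


def test_synchronize_identical_streams(cfg):
    ref_f, ref_p = _force_pose_pair(400.0)
    windows = synchronize_pair(ref_f, ref_p, ref_f, ref_p, cfg)
    assert len(windows) == 2
    for w in windows:
        assert w.peak_time_ref == w.peak_time_test
        assert len(w.rel_times) == 801  # exactly 2 s at 400 Hz
        assert np.allclose(w.ref["Deltoideus middle"], w.test["Deltoideus middle"], atol=1e-9)


def test_synchronize_delayed_test_stream(cfg):
    ref_f, ref_p = _force_pose_pair(400.0)
    test_f, test_p = _force_pose_pair(30.0, delay=0.5)
    windows = synchronize_pair(test_f, test_p, ref_f, ref_p, cfg)
    assert len(windows) == 2
    for w in windows:
        # peaks detected independently, aligned within one camera sample
        assert abs((w.peak_time_test - w.peak_time_ref) - 0.5) <= 1.0 / 30.0
        # after alignment the waveforms coincide closely
        err = np.max(np.abs(w.ref["Deltoideus middle"] - w.test["Deltoideus middle"]))
        assert err < 5.0  # N, on a 100 N waveform


def test_synchronize_five_reps_five_windows(cfg):
    ref_f, ref_p = _force_pose_pair(400.0, n_reps=5)
    windows = synchronize_pair(ref_f, ref_p, ref_f, ref_p, cfg)
    assert len(windows) == 5


def test_synchronize_flat_signal_logs_and_skips(cfg):
    n = 801
    t = np.arange(n) / 400.0
    pose = PoseTrajectory(times=t, coordinates={"shoulder_elevation": np.full(n, 20.0)})
    forces = MuscleForceTrajectory(times=t, forces={"Deltoideus middle": np.zeros(n)})
    log = []
    windows = synchronize_pair(forces, pose, forces, pose, cfg, log=log)
    assert windows == []
    assert any("no detectable" in entry for entry in log)


def test_windows_exceeding_recording_dropped(cfg):
    # lead shorter than the window half-width: the first rep cannot fit
    ref_f, ref_p = _force_pose_pair(400.0, n_reps=1, lead=0.4)
    log = []
    windows = synchronize_pair(ref_f, ref_p, ref_f, ref_p, cfg, log=log)
    assert len(windows) == 1  # peak at lead + rep/2 = 1.65 s still fits
    ref_f2, ref_p2 = _force_pose_pair(400.0, n_reps=1, rep=1.2, lead=0.2)
    log2 = []
    windows2 = synchronize_pair(ref_f2, ref_p2, ref_f2, ref_p2, cfg, log=log2)
    assert windows2 == [] and any("exceeds recording" in e for e in log2)
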