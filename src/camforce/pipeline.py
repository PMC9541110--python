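"""End-to-end study driver: simulate, process both pathways, compare.

Reproduces the study design at synthetic scale: for every subject and trial,
ground-truth exercise kinematics are generated and rendered into a marker
stream and a camera stream; each stream is quality-controlled, scaled from a
static pose, and pushed through the identical inverse-kinematics ->
inverse-dynamics -> static-optimization chain; finally the per-repetition
force windows are compared and aggregated into the validation report.
Excluded trials are logged with their stage and reason; the run continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .inverse_dynamics import compute_net_moments, make_external_load
from .inverse_kinematics import IKSettings, solve_trajectory
from .model_registry import GenericModel, load_default_model
from .preprocess import (
    RegressionCoefficients,
    compute_scales,
    default_regression,
    elevation_from_centers,
    estimate_joint_centers,
    prescribe_scapula_clavicle,
    qc_camera_trial,
    qc_marker_trial,
)
from .static_optimization import MuscleForceTrajectory, SOSettings, solve_trajectory_so
from .synthetic_data import (
    ExerciseProfile,
    NoiseModel,
    generate_ground_truth,
    render_camera_stream,
    render_marker_stream,
)
from .trajectories import PoseTrajectory, TrajectorySet
from .validation_stats import (
    AnalysisConfig,
    PRIME_MOVERS,
    ROW_LABELS,
    ValidationReport,
    aggregate,
    bland_altman,
    compare_windows,
    synchronize_pair,
)

__all__ = ["StudyDesign", "StudyResult", "PathwayResult", "run_study",
           "build_subject_model", "run_pathway", "simulate_trial"]


@dataclass
class StudyDesign:
    """Synthetic stand-in for the study protocol (five participants by default)."""

    n_subjects: int = 5
    exercises: Sequence[ExerciseProfile] = field(
        default_factory=lambda: (ExerciseProfile.lateral_fly(), ExerciseProfile.biceps_curl())
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    marker_rate: float = 400.0
    camera_rate: float = 30.0
    height_sd: float = 0.035  # relative between-subject stature variation
    segment_jitter_sd: float = 0.01  # relative per-segment anthropometry jitter

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    def trial_seed(self, subject: int, exercise_idx: int, set_idx: int) -> int:
        # unique, deterministic, and well below 2**31 for small base seeds
        return (self.seed * 997 + subject * 101 + exercise_idx * 31 + set_idx) % (2**31 - 1)


@dataclass
class PathwayResult:
    pose: PoseTrajectory
    forces: MuscleForceTrajectory


@dataclass
class StudyResult:
    report: ValidationReport
    exclusions: List[dict]
    n_generated: int
    n_included: int
    log: List[str] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return 0 if not self.exclusions else 1


def build_subject_model(
    generic: GenericModel, rng: np.random.Generator,
    height_sd: float = 0.035, jitter_sd: float = 0.01,
) -> Tuple[GenericModel, Dict[str, np.ndarray]]:
    """Anthropometry-varied true model of one subject."""
    stature = float(np.clip(1.0 + height_sd * rng.standard_normal(), 0.9, 1.1))
    factors = {
        seg: stature * np.clip(1.0 + jitter_sd * rng.standard_normal(3), 0.95, 1.05)
        for seg in generic.chain.segments
    }
    return generic.scaled(factors), factors


def simulate_trial(
    profile: ExerciseProfile,
    subject_model: GenericModel,
    noise: NoiseModel,
    seed: int,
    regression: Optional[RegressionCoefficients] = None,
    marker_rate: float = 400.0,
    camera_rate: float = 30.0,
) -> Tuple[PoseTrajectory, TrajectorySet, TrajectorySet]:
    """Ground truth plus both rendered measurement streams for one trial."""
    truth = generate_ground_truth(
        profile, subject_model, seed, rate=marker_rate, regression=regression
    )
    trial_noise = replace(noise, seed=seed)
    marker = render_marker_stream(truth, subject_model, trial_noise)
    camera = render_camera_stream(truth, subject_model, trial_noise, rate=camera_rate)
    return truth, marker, camera


def static_scales(
    subject_model: GenericModel,
    generic: GenericModel,
    noise: NoiseModel,
    seed: int,
    regression: RegressionCoefficients,
    marker_rate: float = 400.0,
    camera_rate: float = 30.0,
):
    """Scale sets for both pathways from a 5 s static neutral-pose trial."""
    n = int(5.0 * marker_rate) + 1
    times = np.arange(n) / marker_rate
    neutral = PoseTrajectory(
        times=times,
        coordinates={c: np.zeros(n) for c in subject_model.chain.coordinate_names},
        meta={"exercise": "static", "rate": marker_rate, "trial_id": "static"},
    )
    static_noise = replace(noise, seed=seed, failure_prob=0.0)
    marker = render_marker_stream(neutral, subject_model, static_noise)
    camera = render_camera_stream(neutral, subject_model, static_noise, rate=camera_rate)
    marker_aug = estimate_joint_centers(marker, regression)
    return compute_scales(marker_aug, generic), compute_scales(camera, generic)


def run_pathway(
    stream: TrajectorySet,
    generic: GenericModel,
    scales,
    regression: RegressionCoefficients,
    profile: ExerciseProfile,
    ik_settings: Optional[IKSettings] = None,
    so_settings: Optional[SOSettings] = None,
    id_filter_cutoff: float = 6.0,
) -> PathwayResult:
    """Scale -> IK -> ID -> SO for one measurement stream.

    The identical settings serve both stream kinds; only the set of labels
    resolving to virtual markers differs.
    """
    ik_settings = ik_settings or IKSettings()
    so_settings = so_settings or SOSettings()
    model = generic.scaled(scales.factors)
    if stream.stream_kind == "marker":
        stream = estimate_joint_centers(stream, regression)
    theta = _fill_nan(elevation_from_centers(stream))
    from .preprocess import coordinate_elevation_from_humerothoracic

    elev = coordinate_elevation_from_humerothoracic(theta, regression)
    partial = PoseTrajectory(
        times=stream.times, coordinates={"shoulder_elevation": elev}
    )
    prescribed = prescribe_scapula_clavicle(partial, regression)
    pose = solve_trajectory(stream, model, ik_settings, prescribed)
    load = make_external_load(profile.dumbbell_mass)
    moments = compute_net_moments(
        pose, model, load, rhythm_slopes=regression.rhythm_slopes,
        filter_cutoff=id_filter_cutoff,
    )
    forces = solve_trajectory_so(
        pose, moments, model, so_settings, rhythm_slopes=regression.rhythm_slopes
    )
    return PathwayResult(pose=pose, forces=forces)


def _fill_nan(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over missing samples (ends held)."""
    x = np.asarray(x, dtype=float).copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("series is entirely missing")
    if bad.any():
        idx = np.arange(len(x))
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def run_study(
    design: StudyDesign,
    generic: Optional[GenericModel] = None,
    regression: Optional[RegressionCoefficients] = None,
    ik_settings: Optional[IKSettings] = None,
    so_settings: Optional[SOSettings] = None,
    n_sets: Optional[int] = None,
    out_dir: Optional[Path] = None,
) -> StudyResult:
    """Execute the full two-pathway study and aggregate the validation report."""
    from . import fileio  # local import: io is optional for in-memory runs

    generic = generic or load_default_model()
    regression = regression or default_regression()
    log: List[str] = []
    exclusions: List[dict] = []
    trials = []
    ba_peaks: Dict[Tuple[str, str], List[Tuple[str, float, float]]] = {}
    n_generated = 0
    n_included = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for s in range(design.n_subjects):
        subject = f"S{s + 1}"
        rng = np.random.default_rng([design.seed, s])
        subject_model, _ = build_subject_model(
            generic, rng, design.height_sd, design.segment_jitter_sd
        )
        m_scales, c_scales = static_scales(
            subject_model, generic, design.noise,
            design.trial_seed(s, 9, 99), regression,
            design.marker_rate, design.camera_rate,
        )
        for e, profile in enumerate(design.exercises):
            cfg = AnalysisConfig.for_exercise(profile.name)
            rows = ROW_LABELS[profile.name]
            sets = n_sets if n_sets is not None else profile.n_sets
            for k in range(sets):
                trial_id = f"{subject}_{profile.name}_set{k + 1}"
                n_generated += 1
                seed = design.trial_seed(s, e, k)
                truth, marker, camera = simulate_trial(
                    profile, subject_model, design.noise, seed, regression,
                    design.marker_rate, design.camera_rate,
                )
                marker.meta["trial_id"] = trial_id
                camera.meta["trial_id"] = trial_id
                qc_m = qc_marker_trial(marker)
                qc_c = qc_camera_trial(camera)
                if not qc_m.included:
                    exclusions.append(
                        {"trial": trial_id, "stage": "qc_marker", "reason": qc_m.reason}
                    )
                    log.append(f"{trial_id}: marker stream excluded ({qc_m.reason})")
                    continue
                if not qc_c.included:
                    exclusions.append(
                        {"trial": trial_id, "stage": "qc_camera", "reason": qc_c.reason}
                    )
                    log.append(f"{trial_id}: camera stream excluded ({qc_c.reason})")
                    continue
                try:
                    ref = run_pathway(
                        marker, generic, m_scales, regression, profile,
                        ik_settings, so_settings,
                    )
                    test = run_pathway(
                        camera, generic, c_scales, regression, profile,
                        ik_settings, so_settings,
                    )
                except Exception as exc:  # any stage failure excludes the trial
                    exclusions.append(
                        {"trial": trial_id, "stage": "pipeline", "reason": str(exc)}
                    )
                    log.append(f"{trial_id}: pipeline failure ({exc})")
                    continue
                if not ref.pose.meta.get("usable", True) or not test.pose.meta.get("usable", True):
                    exclusions.append(
                        {"trial": trial_id, "stage": "ik", "reason": "too many flagged frames"}
                    )
                    continue
                wlog: List[str] = []
                windows = synchronize_pair(
                    test.forces, test.pose, ref.forces, ref.pose, cfg,
                    muscles=rows, log=wlog,
                )
                log.extend(f"{trial_id}: {m}" for m in wlog)
                if not windows:
                    exclusions.append(
                        {"trial": trial_id, "stage": "sync", "reason": "no aligned windows"}
                    )
                    continue
                n_included += 1
                comps = compare_windows(windows, generic, rows)
                trials.extend((subject, profile.name, c) for c in comps)
                for mover in PRIME_MOVERS[profile.name]:
                    key = (profile.name, mover)
                    for w in windows:
                        ba_peaks.setdefault(key, []).append(
                            (subject, float(np.max(w.test[mover])), float(np.max(w.ref[mover])))
                        )
                if out_dir is not None:
                    fileio.write_trc(marker, out_dir / f"{trial_id}_marker.trc")
                    fileio.write_trc(camera, out_dir / f"{trial_id}_camera.trc")
                    fileio.write_pose_sto(ref.pose, out_dir / f"{trial_id}_marker_ik.sto")
                    fileio.write_pose_sto(test.pose, out_dir / f"{trial_id}_camera_ik.sto")
                    fileio.write_sto(
                        ref.forces.times, ref.forces.forces,
                        out_dir / f"{trial_id}_marker_forces.sto", name="muscle_forces",
                    )
                    fileio.write_sto(
                        test.forces.times, test.forces.forces,
                        out_dir / f"{trial_id}_camera_forces.sto", name="muscle_forces",
                    )

    if trials:
        report = aggregate(trials)
    else:
        report = ValidationReport(rows=[])
    report.n_trials_included = n_included
    report.n_trials_excluded = len(exclusions)
    report.exclusions = exclusions
    for key, entries in ba_peaks.items():
        subjects = [s for s, _, _ in entries]
        tests = [t for _, t, _ in entries]
        refs = [r for _, _, r in entries]
        if len(tests) >= 2:
            report.bland_altman[key] = bland_altman(tests, refs, subjects=subjects)
    report.meta = {
        "seed": design.seed,
        "n_subjects": design.n_subjects,
        "noise_sigma_xy_m": design.noise.sigma_xy,
    }
    result = StudyResult(
        report=report,
        exclusions=exclusions,
        n_generated=n_generated,
        n_included=n_included,
        log=log,
    )
    if out_dir is not None:
        (out_dir / "report.txt").write_text(report.to_text() + "\n")
        report.to_frame().to_csv(out_dir / "report.csv", index=False)
    return result
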