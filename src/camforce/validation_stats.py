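"""Agreement statistics between the camera and marker force pathways.

For each repetition, the camera-based muscle-force series is up-sampled to
the marker rate, synchronized at the movement peak (peak shoulder elevation
for the lateral fly, peak elbow flexion for the biceps curl), windowed to
one second on either side of the peak, and low-pass filtered (2nd-order
Butterworth, 4 Hz, zero-phase).  Per window the pipeline reports the RMSD in
Newton and as a percentage of the group maximum isometric force, and the
Pearson correlation with the conventional weak / moderate / strong /
excellent category bounds (0.35 / 0.67 / 0.90).  Windows aggregate to
subject means and then to an unweighted grand mean with a between-subject
SD.  Peak forces of the prime movers feed a Bland-Altman agreement analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .model_registry import GenericModel, group_f_max
from .static_optimization import MuscleForceTrajectory
from .trajectories import PoseTrajectory

__all__ = [
    "AnalysisConfig",
    "TrialComparison",
    "AlignedWindow",
    "BlandAltmanResult",
    "ReportRow",
    "ValidationReport",
    "synchronize_pair",
    "resample_to_reference",
    "filter_forces",
    "trial_statistics",
    "aggregate",
    "bland_altman",
    "bland_altman_plot",
    "categorize_r",
    "pct_bw_to_newton",
    "pct_fmax",
    "row_forces",
    "LATERAL_FLY_ROWS",
    "BICEPS_CURL_ROWS",
    "PRIME_MOVERS",
]

#: Report rows per exercise (aggregated head groups use base names).
LATERAL_FLY_ROWS = [
    "Deltoideus middle",
    "Deltoideus anterior",
    "Deltoideus posterior",
    "Trapezius scapula superior",
    "Trapezius scapula middle",
    "Trapezius scapula inferior",
    "Infraspinatus",
    "Teres minor",
    "Subscapularis",
    "Supraspinatus",
]
BICEPS_CURL_ROWS = [
    "Biceps brevis",
    "Biceps long",
    "Triceps",
    "Infraspinatus",
    "Teres minor",
    "Subscapularis",
    "Supraspinatus",
]
PRIME_MOVERS = {
    "lateral_fly": ["Deltoideus middle", "Deltoideus anterior", "Trapezius scapula superior"],
    "biceps_curl": ["Biceps brevis", "Biceps long"],
}
ROW_LABELS = {"lateral_fly": LATERAL_FLY_ROWS, "biceps_curl": BICEPS_CURL_ROWS}

_SYNC_COORD = {
    "peak_shoulder_elevation": "shoulder_elevation",
    "peak_elbow_flexion": "elbow_flexion",
}


@dataclass
class AnalysisConfig:
    sync_event: str = "peak_shoulder_elevation"
    window_halfwidth: float = 1.0  # s
    filter_order: int = 2
    filter_cutoff: float = 4.0  # Hz
    target_rate: float = 400.0  # Hz
    r_bounds: Tuple[float, float, float] = (0.35, 0.67, 0.90)
    ba_loa_multiplier: float = 1.96
    min_filter_samples: int = 20

    def __post_init__(self) -> None:
        if self.filter_cutoff >= self.target_rate / 2:
            raise ValueError("filter cutoff must be below the Nyquist rate")
        b = self.r_bounds
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("r bounds must be strictly increasing in (0, 1)")

    @property
    def sync_coordinate(self) -> str:
        try:
            return _SYNC_COORD[self.sync_event]
        except KeyError:
            raise ValueError(f"unknown sync_event {self.sync_event!r}") from None

    @staticmethod
    def for_exercise(name: str, **overrides) -> "AnalysisConfig":
        event = (
            "peak_elbow_flexion" if name == "biceps_curl" else "peak_shoulder_elevation"
        )
        return AnalysisConfig(sync_event=event, **overrides)


@dataclass
class TrialComparison:
    """Agreement statistics of one repetition window for one report row."""

    muscle: str
    rmsd_N: float
    rmsd_pct_fmax: float
    pearson_r: float  # NaN when undefined (zero-variance window)
    peak_ref: float
    peak_test: float

    def __post_init__(self) -> None:
        if self.rmsd_N < 0:
            raise ValueError("RMSD must be >= 0")
        if not math.isnan(self.pearson_r) and not -1 <= self.pearson_r <= 1 + 1e-12:
            raise ValueError("Pearson r out of range")


@dataclass
class AlignedWindow:
    """One repetition's peak-aligned force windows on the reference grid."""

    rel_times: np.ndarray  # s, relative to the aligned peaks
    ref: Dict[str, np.ndarray]
    test: Dict[str, np.ndarray]
    peak_time_ref: float
    peak_time_test: float


def pct_fmax(rmsd_n: float, fmax_group: float) -> float:
    """RMSD expressed as a percentage of the group maximum isometric force."""
    return 100.0 * rmsd_n / fmax_group


def pct_bw_to_newton(pct_bw: float, body_mass_kg: float, g: float = 9.81) -> float:
    """Convert a force reported in percent body weight to Newton."""
    return pct_bw / 100.0 * body_mass_kg * g


def categorize_r(r: float, bounds: Tuple[float, float, float] = (0.35, 0.67, 0.90)) -> str:
    """Correlation category on |r|: weak / moderate / strong / excellent."""
    if math.isnan(r):
        return "undefined"
    a = abs(r)
    if a <= bounds[0]:
        return "weak"
    if a <= bounds[1]:
        return "moderate"
    if a <= bounds[2]:
        return "strong"
    return "excellent"


def row_forces(forces: Mapping[str, np.ndarray], label: str) -> np.ndarray:
    """Force series of a report row: a column, or the sum of matching heads."""
    if label in forces:
        return forces[label]
    heads = [k for k in forces if k.startswith(label + " ")]
    if not heads:
        raise KeyError(f"no force column matches row {label!r}")
    return np.sum([forces[k] for k in heads], axis=0)


# ---------------------------------------------------------------------------
# resampling / filtering


def resample_to_reference(
    times: np.ndarray,
    values: np.ndarray,
    cfg: AnalysisConfig,
    target_times: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic-spline up-sampling onto the reference (marker-rate) grid.

    Without explicit ``target_times`` the grid spans the input interval with
    ``round(span * target_rate) + 1`` samples, so a 2 s window at 30 Hz (61
    samples) maps to 801 samples at 400 Hz.  Endpoints are preserved exactly.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 4:
        raise ValueError("need at least 4 samples for cubic-spline resampling")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if target_times is None:
        span = times[-1] - times[0]
        n_out = int(round(span * cfg.target_rate)) + 1
        target_times = times[0] + np.arange(n_out) * (span / (n_out - 1))
    spline = CubicSpline(times, values)
    out = spline(target_times)
    # exact endpoint preservation against rounding of the grid arithmetic
    if target_times[0] == times[0]:
        out[0] = values[0]
    if target_times[-1] == times[-1]:
        out[-1] = values[-1]
    return target_times, out


def filter_forces(values: np.ndarray, rate: float, cfg: AnalysisConfig) -> np.ndarray:
    """Zero-phase low-pass Butterworth filtering of a force series."""
    values = np.asarray(values, dtype=float)
    if rate <= 2 * cfg.filter_cutoff:
        raise ValueError("sample rate must exceed twice the filter cutoff")
    if len(values) < cfg.min_filter_samples:
        raise ValueError(
            f"series of {len(values)} samples is shorter than the filter "
            f"warm-up ({cfg.min_filter_samples})"
        )
    sos = signal.butter(cfg.filter_order, cfg.filter_cutoff, fs=rate, output="sos")
    return signal.sosfiltfilt(sos, values)


# ---------------------------------------------------------------------------
# synchronization


def _find_rep_peaks(series: np.ndarray, rate: float) -> np.ndarray:
    """Indices of repetition peaks: prominent maxima above mid-range."""
    lo, hi = float(np.min(series)), float(np.max(series))
    if hi - lo < 1e-6:  # flat signal: no detectable peak
        return np.array([], dtype=int)
    height = lo + 0.5 * (hi - lo)
    distance = max(1, int(0.5 * rate))
    peaks, _ = signal.find_peaks(series, height=height, distance=distance)
    return peaks


def synchronize_pair(
    test_forces: MuscleForceTrajectory,
    test_pose: PoseTrajectory,
    ref_forces: MuscleForceTrajectory,
    ref_pose: PoseTrajectory,
    cfg: AnalysisConfig,
    muscles: Optional[Sequence[str]] = None,
    log: Optional[list] = None,
) -> List[AlignedWindow]:
    """Peak-aligned, filtered force windows for every matched repetition.

    Peaks of the synchronization coordinate are located independently in each
    stream and paired in order; each pair contributes a window of
    ``window_halfwidth`` seconds on either side of the peak on the reference
    grid, with the test stream spline-resampled about its own peak.  Windows
    that do not fit inside either recording are dropped with a log entry.
    """
    log = log if log is not None else []
    coord = cfg.sync_coordinate
    ref_rate = ref_pose.rate
    ref_peaks_idx = _find_rep_peaks(ref_pose.coordinates[coord], ref_rate)
    ref_peak_times = ref_pose.times[ref_peaks_idx]
    # peak instants of the test stream are located on an up-sampled copy of
    # the synchronization coordinate, so 30 Hz sampling does not quantize
    # the alignment
    if test_pose.rate < cfg.target_rate and len(test_pose.times) >= 4:
        fine_t, fine = resample_to_reference(
            test_pose.times, test_pose.coordinates[coord], cfg
        )
    else:
        fine_t, fine = test_pose.times, test_pose.coordinates[coord]
    fine_rate = 1.0 / float(np.mean(np.diff(fine_t))) if len(fine_t) > 1 else 1.0
    test_peaks_idx = _find_rep_peaks(fine, fine_rate)
    test_peak_times = fine_t[test_peaks_idx]
    if len(ref_peak_times) == 0 or len(test_peak_times) == 0:
        log.append(f"no detectable {coord} peak; no windows extracted")
        return []
    if len(ref_peak_times) != len(test_peak_times):
        log.append(
            f"peak count mismatch (ref {len(ref_peak_times)}, "
            f"test {len(test_peak_times)}); pairing in order"
        )
    if muscles is None:
        muscles = [k for k in ref_forces.forces if k in test_forces.forces]
    h = cfg.window_halfwidth
    half_n = int(round(h * ref_rate))
    windows: List[AlignedWindow] = []
    for rp, t_test in zip(ref_peaks_idx, test_peak_times):
        t_ref = ref_pose.times[rp]
        if rp - half_n < 0 or rp + half_n >= len(ref_pose.times):
            log.append(f"window at ref peak {t_ref:.2f}s exceeds recording; dropped")
            continue
        rel = (np.arange(-half_n, half_n + 1)) / ref_rate
        target_test = t_test + rel
        if target_test[0] < test_forces.times[0] or target_test[-1] > test_forces.times[-1]:
            log.append(f"window at test peak {t_test:.2f}s exceeds recording; dropped")
            continue
        ref_win = {}
        test_win = {}
        for mus in muscles:
            r_series = row_forces(ref_forces.forces, mus)[rp - half_n : rp + half_n + 1]
            _, t_series = resample_to_reference(
                test_forces.times, row_forces(test_forces.forces, mus), cfg, target_test
            )
            ref_win[mus] = filter_forces(r_series, ref_rate, cfg)
            test_win[mus] = filter_forces(t_series, ref_rate, cfg)
        windows.append(
            AlignedWindow(
                rel_times=rel,
                ref=ref_win,
                test=test_win,
                peak_time_ref=float(t_ref),
                peak_time_test=float(t_test),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# statistics


def trial_statistics(
    test_window: np.ndarray,
    ref_window: np.ndarray,
    fmax_group: float,
    muscle: str = "",
) -> TrialComparison:
    """RMSD (N and %Fmax), Pearson r and peak forces of one aligned window.

    The RMSD is the root of the frame-averaged squared deviation.  Pearson r
    is recorded as NaN (missing) when either window has zero variance.
    """
    test_window = np.asarray(test_window, dtype=float)
    ref_window = np.asarray(ref_window, dtype=float)
    if test_window.shape != ref_window.shape:
        raise ValueError("windows must be equal length")
    dev = test_window - ref_window
    rmsd = float(np.sqrt(np.mean(dev**2)))
    if np.std(test_window) < 1e-12 or np.std(ref_window) < 1e-12:
        r = float("nan")
    else:
        r = float(np.corrcoef(ref_window, test_window)[0, 1])
    return TrialComparison(
        muscle=muscle,
        rmsd_N=rmsd,
        rmsd_pct_fmax=pct_fmax(rmsd, fmax_group),
        pearson_r=r,
        peak_ref=float(np.max(ref_window)),
        peak_test=float(np.max(test_window)),
    )


@dataclass
class BlandAltmanResult:
    bias: float  # N, mean(test - ref)
    sd: float  # N, sample SD (n-1) of the differences
    loa: Tuple[float, float]  # limits of agreement
    means: np.ndarray  # pairwise means (plot abscissa)
    differences: np.ndarray
    per_subject_bias: Dict[str, float] = field(default_factory=dict)


def bland_altman(
    peaks_test: Sequence[float],
    peaks_ref: Sequence[float],
    cfg: Optional[AnalysisConfig] = None,
    subjects: Optional[Sequence[str]] = None,
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired peak forces (test - ref).

    Limits of agreement are ``bias +/- 1.96 * SD`` with the sample SD
    (n-1 denominator).  Per-subject mean differences support checking
    between-subject consistency of the measurement error.
    """
    cfg = cfg or AnalysisConfig()
    t = np.asarray(peaks_test, dtype=float)
    r = np.asarray(peaks_ref, dtype=float)
    if t.shape != r.shape:
        raise ValueError("paired peak lists must have equal length")
    if len(t) < 2:
        raise ValueError("need at least 2 paired peaks")
    diff = t - r
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    k = cfg.ba_loa_multiplier
    per_subject = {}
    if subjects is not None:
        for s in sorted(set(subjects)):
            sel = np.asarray([su == s for su in subjects])
            per_subject[s] = float(np.mean(diff[sel]))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa=(bias - k * sd, bias + k * sd),
        means=0.5 * (t + r),
        differences=diff,
        per_subject_bias=per_subject,
    )


def bland_altman_plot(result: "BlandAltmanResult", path, title: str = "") -> None:
    """Write a Bland-Altman scatter (difference vs. pairwise mean) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=18, alpha=0.8)
    ax.axhline(result.bias, color="k", lw=1, label=f"bias {result.bias:+.1f} N")
    for lim in result.loa:
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of methods (N)")
    ax.set_ylabel("camera - marker (N)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class ReportRow:
    exercise: str
    muscle: str
    rmsd_n_mean: float
    rmsd_n_sd: float
    rmsd_pct_mean: float
    rmsd_pct_sd: float
    r_mean: float
    r_sd: float
    r_category: str
    n_subjects: int
    n_windows: int
    n_r_missing: int


@dataclass
class ValidationReport:
    """Grand-mean agreement table plus Bland-Altman summaries and trial counts."""

    rows: List[ReportRow]
    bland_altman: Dict[Tuple[str, str], BlandAltmanResult] = field(default_factory=dict)
    n_trials_included: int = 0
    n_trials_excluded: int = 0
    exclusions: List[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "exercise": r.exercise,
                    "muscle": r.muscle,
                    "rmsd_N_mean": round(r.rmsd_n_mean, 1),
                    "rmsd_N_sd": round(r.rmsd_n_sd, 1),
                    "rmsd_pct_fmax_mean": round(r.rmsd_pct_mean, 1),
                    "rmsd_pct_fmax_sd": round(r.rmsd_pct_sd, 1),
                    "r_mean": round(r.r_mean, 2),
                    "r_sd": round(r.r_sd, 2),
                    "r_category": r.r_category,
                    "n_subjects": r.n_subjects,
                    "n_windows": r.n_windows,
                }
                for r in self.rows
            ]
        )

    def to_text(self) -> str:
        lines = [
            "Muscle-force agreement, camera vs marker pathway",
            "(grand mean +/- between-subject SD)",
            "",
        ]
        frame = self.to_frame()
        lines.append(frame.to_string(index=False))
        lines.append("")
        lines.append(
            f"windows included: {self.n_trials_included}; "
            f"trials excluded: {self.n_trials_excluded}"
        )
        for (exercise, muscle), ba in self.bland_altman.items():
            lines.append(
                f"Bland-Altman {exercise}/{muscle}: bias {ba.bias:+.1f} N, "
                f"LoA [{ba.loa[0]:.1f}, {ba.loa[1]:.1f}] N"
            )
        return "\n".join(lines)


def aggregate(
    trials: Sequence[Tuple[str, str, TrialComparison]],
    r_bounds: Tuple[float, float, float] = (0.35, 0.67, 0.90),
) -> ValidationReport:
    """Trial -> subject -> grand aggregation of comparison windows.

    ``trials`` holds ``(subject_id, exercise, comparison)`` entries.  For
    every (exercise, muscle) row the subject means are averaged with equal
    weight; the reported SD is the between-subject SD of those means (0 for a
    single subject).  Missing correlations (zero-variance windows) are
    excluded from the r mean but counted.
    """
    if not trials:
        raise ValueError("no trials to aggregate")
    by_row: Dict[Tuple[str, str], Dict[str, List[TrialComparison]]] = {}
    for subject, exercise, comp in trials:
        by_row.setdefault((exercise, comp.muscle), {}).setdefault(subject, []).append(comp)
    rows = []
    for (exercise, muscle), per_subject in sorted(by_row.items()):
        def subject_means(attr):
            means = []
            for comps in per_subject.values():
                vals = [getattr(c, attr) for c in comps]
                vals = [v for v in vals if not math.isnan(v)]
                if vals:
                    means.append(float(np.mean(vals)))
            return np.asarray(means)

        rmsd_means = subject_means("rmsd_N")
        pct_means = subject_means("rmsd_pct_fmax")
        r_means = subject_means("pearson_r")
        n_windows = sum(len(c) for c in per_subject.values())
        n_r_missing = sum(
            1 for comps in per_subject.values() for c in comps if math.isnan(c.pearson_r)
        )

        def mean_sd(arr):
            if len(arr) == 0:
                return float("nan"), float("nan")
            m = float(np.mean(arr))
            s = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
            return m, s

        rm, rs = mean_sd(rmsd_means)
        pm, ps = mean_sd(pct_means)
        cm, cs = mean_sd(r_means)
        rows.append(
            ReportRow(
                exercise=exercise,
                muscle=muscle,
                rmsd_n_mean=rm,
                rmsd_n_sd=rs,
                rmsd_pct_mean=pm,
                rmsd_pct_sd=ps,
                r_mean=cm,
                r_sd=cs,
                r_category=categorize_r(cm, r_bounds),
                n_subjects=len(per_subject),
                n_windows=n_windows,
                n_r_missing=n_r_missing,
            )
        )
    return ValidationReport(rows=rows)


def compare_windows(
    windows: Sequence[AlignedWindow],
    model: GenericModel,
    row_labels: Sequence[str],
) -> List[TrialComparison]:
    """Per-window agreement statistics for the configured report rows."""
    out = []
    for w in windows:
        for label in row_labels:
            fmax = group_f_max(label, model)
            out.append(
                trial_statistics(w.test[label], w.ref[label], fmax, muscle=label)
            )
    return out
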