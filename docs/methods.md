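# Methods

This note documents the models, numerical choices and limitations of
`camforce`. It covers what each stage computes, which parameters matter and
why their defaults were chosen, and what the synthetic-data generator does
and does not emulate.

## Kinematic chain and muscle registry

The chain is thorax (fixed at the origin; world frame X right, Y up,
Z forward, gravity −Y) → clavicle → scapula → humerus → forearm → hand.

* Clavicle (2 coordinates) and scapula (3 coordinates) are *prescribed*:
  they are not solved freely but driven by a linear scapulohumeral-rhythm
  stand-in (below).
* The glenohumeral joint has three rotational coordinates as an intrinsic
  Y–Z–Y sequence: elevation plane, elevation, axial rotation. Elbow flexion
  (about −X) and forearm pronation–supination (about the forearm long axis)
  complete the five free coordinates; the wrist is rigid.
* The scapula's joint center is placed **at** the glenohumeral center and
  the acromion virtual marker rides the distal clavicle. Consequence: with a
  neutral clavicle the glenohumeral center sits at a constant offset
  (0, −0.045, 0) m from the acromion, which is exactly the regression used
  to estimate the shoulder joint center from markers. This is an artifact
  design choice that makes the joint-center regression self-consistent in
  the synthetic world; in real data the same regression carries
  centimeter-level errors.

The muscle registry holds 33 aggregated shoulder/elbow bundles with their
published maximum isometric forces, optimal fiber lengths, tendon slack
lengths and pennation angles. Head groups (e.g. the two infraspinatus or
three subscapularis heads) aggregate by summing forces, and %F_max
normalizers sum the head F_max values; this convention reproduces the
printed percentage columns of the source registry at 1-decimal rounding for
every single-head and rotator-cuff row (one published biceps row is
internally inconsistent by 0.1% and is flagged rather than reconciled).

Muscle geometry is a straight-line path-point asset. Two properties were
engineered, not copied from anatomy:

* **Sign-stable moment arms.** Near-joint via points make chord moment arms
  flip sign inside the exercise range (a known pathology of straight-line
  paths), so crossing segments run between attachment sites at segment-scale
  radii whose angular separation stays inside (0°, 180°) over the whole
  motion range. Arms are computed by tendon excursion, the central finite
  difference −ΔL/Δq over a 0.1° span.
* **Calibrated operating lengths.** Each path was slid along its own line of
  action (preserving moment arms) until, at a mid-range reference pose
  (40° elevation, 60° elbow flexion, rhythm applied), the musculotendon
  length equals ℓ_ts + ℓ_opt·cos α, i.e. normalized fiber length 1. Fiber
  lengths follow the rigid-tendon relation (L − ℓ_ts)/cos α, floored at
  0.01·ℓ_opt with a flag.

Segment inertia defaults (upper arm 2.2 kg, forearm 1.3 kg, hand 0.5 kg,
with literature-style center-of-mass offsets and principal moments) are
configurable in the model asset; thorax, clavicle and scapula carry no mass
because the thorax is fixed and girdle dynamics are negligible for these
slow exercises. The hand's center of mass lies on the forearm long axis — a
centered dumbbell grip — so gravity produces no pronation moment.

## Scapulohumeral rhythm

The five girdle coordinates are affine functions of humeral elevation;
default: scapular upward rotation = elevation/2, all other slopes and
intercepts 0. These are configurable stand-ins, not reprinted literature
regressions. Two consequences worth noting:

* **Coupling moment arms.** Scapulothoracic muscles (trapezius, serratus,
  rhomboids, ...) cross no free joint, yet they act on shoulder elevation
  because perturbing elevation drags the prescribed scapula along the
  rhythm. Moment arms and inverse-dynamics Jacobians both include this
  coupling, so moments and muscle torques share one convention.
* **Coordinate vs. humerothoracic angle.** The elevation measured from
  joint centers (shoulder→elbow vector vs. vertical) is the humerothoracic
  angle θ = e + s (coordinate plus colinear scapular rotation). The
  estimator inverts the rhythm, e = (θ − intercept)/(1 + slope), before
  prescribing the girdle, so generation and estimation agree exactly in the
  noise-free case.

## Synthetic data

Ground truth drives each exercise's coordinates with raised-cosine
repetition profiles (single maximum at mid-rep, C² smooth): lateral fly
15°→90°→15° shoulder elevation with a near-extended elbow and a 3 kg
dumbbell; biceps curl 10°→130°→10° elbow flexion with near-neutral shoulder
and 5 kg. Default protocol: 3 sets × 5 repetitions, 2.5 s per repetition
(self-selected pace stand-in), 30 s rest between sets, five subjects with
±3.5% stature variation and ±1% per-segment jitter. A seeded ±3% per-rep
amplitude jitter emulates pacing variability.

The marker stream is forward kinematics of 12 landmarks at 400 Hz plus
isotropic white noise (default sd 1 mm) and independent per-frame dropout.
The camera stream is forward kinematics of 5 joint centers at 30 Hz plus
stationary AR(1) noise (default lag-1 correlation 0.9; in-plane sd 20 mm;
depth sd 2× that, because monocular lifting degrades depth most); the
defaults put the mean per-joint position error in the 23–47 mm range
reported for monocular pose lifting. With per-trial probability
`failure_prob` the whole trial collapses to a tiny skeleton (all
inter-center distances < 0.1 m) to exercise quality control.

**What the generator does not emulate.** Real pose-estimation errors are
spatially structured (whole-limb displacements, systematic depth biases,
occlusion-correlated failures), whereas this generator draws noise
independently per joint center. Independent noise of the same magnitude
fluctuates segment lengths and joint angles far more than structured noise
does, so validation statistics under the default noise are *pessimistic*:
they bound the pipeline's behavior under worst-case unstructured error and
should not be read as a prediction of a real camera system's agreement.
Soft-tissue artifact, marker mislabeling and image-space effects (lighting,
occlusion by equipment) are likewise not modeled.

## Scaling

Per-segment scale factors come from a 5 s static neutral pose: the ratio of
the measured to generic distance of configured virtual-marker pairs. The
measured distance is taken between *time-averaged* positions (not the
average of per-frame distances), which removes most of the upward bias that
norm-of-noisy-vector estimators suffer; with the temporally correlated
camera noise the residual bias on a 0.3 m segment is below 1%. Marker-based
pairs resolve separate axes where the marker set allows; every camera pair
is isotropic, so in particular the thorax scales uniformly from its single
length pair — the sparse-stream limitation of markerless scaling.

## Inverse kinematics

Per frame, all ten chain coordinates minimize marker error (m²) plus
`angle_weight = 10` times the squared deviation (rad²) of the five girdle
coordinates from their rhythm targets, plus small quadratic priors toward
neutral on humeral axial rotation and forearm rotation (weight 0.01) and on
the elevation plane (0.001). The priors resolve coordinates that
joint-center-only input cannot observe (an extended elbow puts the wrist
center on the humeral axis); they are part of the settings object and are
recorded in the output metadata. The solver is a damped Gauss–Newton
(Levenberg-style) iteration with a forward-difference Jacobian,
warm-started from the previous frame; it accepts only improving steps, so
the objective never exceeds the warm-start objective. Joint limits are a
soft clamp with a per-frame flag; frames with fewer than three usable
points carry the warm start forward and are flagged; a trial with more than
50% flagged frames is unusable.

## Inverse dynamics

Generalized moments for the free coordinates are assembled from Newton–Euler
segment wrenches mapped through finite-difference Jacobians (step 10⁻³ rad),
which is algebraically the recursive Newton–Euler result for a fixed-base
chain. Coordinates are low-pass filtered (2nd-order Butterworth, 6 Hz,
zero-phase) before central-difference velocities and accelerations — a
smoothing choice distinct from the 4 Hz force filter applied in the
validation stage. The dumbbell is a pure force at the hand's center of mass
(its own rotational inertia is neglected, consistent with slow lifts). The
per-frame inertial fraction (share of acceleration terms in the moment
norm) is reported as a quasi-staticity diagnostic; for repetitions ≥ 2 s it
stays below a few percent at the peak-moment frame.

## Static optimization

Each frame solves

    min Σ aᵢ² + w_res Σ r_j²
    s.t. Σ aᵢ · f_L(ℓ̃ᵢ) · F_max,i · cos αᵢ · R_ij + r_j = M_j,  0 ≤ aᵢ ≤ 1

an exactly solvable bounded ridge least-squares problem; the implementation
is a primal active-set iteration (Lawson–Hanson style with upper bounds)
with a generic bounded solver as fallback, verified in tests against
exhaustive grid search and exact bound-pattern enumeration. Reserve
actuators with weight `w_res = 1000` guarantee feasibility; a frame is
flagged infeasible when any |r_j| exceeds 0.01·|M_j| + 0.1 N·m, and a trial
with more than 10% infeasible frames is flagged. The force-length curve is
a Gaussian of width 0.45 in normalized fiber length (toggleable to an
ideal-force mode, f_L = 1; the active mode is recorded in output metadata).
Force-velocity scaling is omitted — rigid tendon, slow movements.

Constrained coordinates are the three shoulder coordinates and elbow
flexion. Forearm rotation is *not* moment-balanced: the registry contains
no pronator, so whenever the biceps are active their supination torque
could never be cancelled and the constraint would be structurally
infeasible; the coordinate is instead regularized in IK and carries
essentially no gravity moment (hand mass centered on the forearm axis).
The prescribed girdle coordinates are not moment-constrained either —
scapulothoracic muscles contribute through the elevation coupling only —
which is the major simplification relative to full thoracoscapular models.

## Validation statistics

Repetition peaks of the synchronization coordinate (shoulder elevation for
the fly, elbow flexion for the curl) are located independently in each
stream — on a spline-up-sampled copy for the 30 Hz stream, so peak timing
is not quantized to camera samples — and paired in order. Each pair yields
±1 s windows on the 400 Hz grid (801 samples), the camera force series
being cubic-spline resampled about its own peak; both windows are filtered
with a zero-phase 2nd-order 4 Hz Butterworth. Per window the pipeline
reports RMSD (N), RMSD/%F_max, Pearson r (recorded missing for
zero-variance windows rather than zero, since near-constant stabilizer
forces make r meaningless), and the peak forces of the prime movers for
Bland–Altman analysis (bias ± 1.96 × sample SD of the paired differences,
with per-subject mean differences to expose between-subject
inconsistency). Aggregation is repetition → subject mean → unweighted grand
mean, with the between-subject SD of subject means (0 for one subject).
Report tables round to 1 decimal (N, %) and 2 decimals (r).

## Problem sizes and determinism

Every random quantity is drawn from seeded generators; identical seeds give
byte-identical reports. The packaged acceptance script exercises the full
study machinery at desk scale — two-repetition trials, one to three trials
per condition, two noise realizations per trial in the 0/10/20/40 mm noise
sweep — sizes chosen so the whole script completes in minutes on one CPU
while every stage runs at its native rates (400 Hz marker, 30 Hz camera).
The full five-subject, 3 × 5-repetition protocol runs unchanged through the
same entry points when more compute is available.

## Known limitations

* Straight-line muscle paths without wrapping surfaces; moment arms are
  plausible, not subject-specific. All force comparisons are internal
  (camera vs. marker pathway through identical geometry), so geometry
  realism affects face validity, not the validity of the comparison.
* The scapulothoracic gliding constraint is replaced by the prescribed
  rhythm; girdle muscles act only through the rhythm coupling.
* The camera noise model is unstructured (see above); real-system agreement
  statistics cannot be inferred from the synthetic ones.
* No glenohumeral stability constraint, no EMG-informed recruitment, no
  dynamic optimization.
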