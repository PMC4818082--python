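# Methods

## The physical system

The manipulated object is a virtual planar double pendulum moving in the
horizontal plane (no gravity): two rigid links joined by revolute joints,
with a fixed pivot ("shoulder") at the workspace origin. Default mechanical
constants: link masses m₁ = m₂ = 10 kg, lengths l₁ = l₂ = 0.2 m, rotational
inertias I₁ = I₂ = 0.4 kg·m² about the mid-link centers of mass
(c₁ = c₂ = 0.1 m). An isotropic alternative object is a 15 kg point mass.

Angle convention: q₁ is the absolute angle of the proximal link from the
workspace x-axis and q₂ the elbow angle of the distal link relative to the
proximal one. With the three inertial constants

    a = I₁ + m₁c₁² + I₂ + m₂(l₁² + c₂²),   b = m₂l₁c₂,   d = I₂ + m₂c₂²,

the mass matrix is

    M(q₂) = [[a + 2b cos q₂, d + b cos q₂],
             [d + b cos q₂,  d          ]],

symmetric positive definite everywhere and — by construction of the
convention — a function of the elbow angle alone. The unforced dynamics are
M(q)q̈ + C(q, q̇)q̇ = 0 with the standard Coriolis/centripetal term; total
energy is purely kinetic, E = ½ q̇ᵀM q̇.

The hand couples to the object's endpoint through a virtual spring-damper
(admittance-style haptic rendering): F = K(x_hand − x_end) + B(v_hand −
v_end) with K = 2200 N/m and B = 65 N·s/m. F is the force applied *to the
object*, and the mechanical work transferred over a maneuver is

    E = ∫₀ᵀ |F·v| dt,

with v the hand velocity (for purely simulated optimal trajectories, the
object-endpoint velocity stands in for the hand's — the two coincide in the
stiff-coupling limit).

With these constants the coupled hand–object mode is underdamped
(ζ ≈ 0.15, ring-down time ≈ 0.6 s), so a spring lag of a few millimeters
persists through a 500 ms target hold; this is physical, not a solver
artifact.

## Integrators

* Coupled (driven) simulation: fixed-step classical RK4 at dt = 1 ms — the
  haptic loop rate — with hand samples linearly interpolated at half-steps;
  output decimated to the 100 Hz recording rate. Verified by energy
  conservation in the K = B = 0 limit (< 1e-6 relative over 1 s).
* Unforced flow: the same RK4 kernel, or an adaptive DOP853 integration
  (rtol 1e-12) when high-accuracy conservation is wanted; measured relative
  energy drift is < 1e-10 over 1 s for both.

## Path of least kinetic energy (geodesic)

The mass matrix, read as a Riemannian metric on configuration space, makes
unforced motions geodesics. The least-energy path between two endpoint
positions is therefore computed as a two-point boundary value problem of the
unforced system with free boundary velocities: single shooting over the
initial joint velocity (2 unknowns, 2 boundary equations, hybrid
Powell root-finder), with a fixed nominal duration of 1 s — geodesics are
invariant to this time normalization, and the tests assert the path shape is
unchanged when the traversal speed is rescaled. Multi-start over 8 rotated
initial-velocity directions and both elbow branches of the inverse
kinematics; among converged solutions (boundary residual < 1e-8 rad) the one
with the smallest discretized path energy Σ Δqᵀ M(q̄) Δq wins. Non-convergence
raises an explicit error carrying the best residual.

An independent solver, `waypoint_geodesic_path`, minimizes the same
discretized energy functional directly over a 50-waypoint joint-space
polyline (analytic gradient, L-BFGS) without ever integrating the dynamics;
the two routes agree to < 5 mm in discrete Fréchet distance on random
task-scale target pairs. For the point mass the metric is Euclidean and the
geodesic is returned as the straight segment.

## Effort-optimal trajectory

The admissible (rest-to-rest) trajectory minimizing the integral cost of the
applied force. Because the object is fully actuated, the problem is solved
in "inverse-dynamics" (flatness) form rather than by collocation: the joint
trajectory is parametrized as a minimum-jerk baseline between the boundary
configurations plus K smooth modes sin(πτ)sin(kπτ) per joint — each
vanishing with zero slope at both ends, so boundary positions and the
rest-to-rest conditions hold by construction — and the applied endpoint
force follows from u = J⁻ᵀ(M q̈ + C q̇). The effort ∫‖u‖²dt (default; ∫‖u‖dt
available as `cost_form="abs"`) is minimized over the mode coefficients with
L-BFGS, i.e. literally gradient descent starting from the straight-line
trajectory; the recorded cost history is monotonically non-increasing.
Defaults: 6 modes per joint, 241 quadrature points (6·n_knots + 1 with
n_knots = 40), both elbow branches tried. The resulting spatial paths track
the geodesics to within ~2 % of the target separation, and their work
integral is strictly below that of a spring-driven straight minimum-jerk
hand motion for every target pair (≈ 0.78 J vs ≈ 1.08 J at the default
layout).

Squared effort was chosen as the primary cost because it is smooth and the
conventional reading of "integrated force" costs; the absolute form is kept
as a configuration option and converges to essentially the same shapes.

## Trajectory statistics

* **Discrete Fréchet distance (DFD)** — the minimax leash length over
  order-preserving couplings of two point sequences, by the standard
  dynamic program; exact against exhaustive coupling enumeration on paths of
  ≤ 6 points, symmetric, invariant under shared rigid motions, and bounded
  below by the discrete Hausdorff distance.
* **Segmentation** — movement onset/offset at 10 % of peak speed; speed is
  taken from central differences at 100 Hz and smoothed with a 5-sample
  moving average (the window is configurable; mild smoothing prevents
  spurious onsets on noisy data). Trials with zero peak speed are excluded,
  never imputed.
* **Time normalization** — clipped trials resampled at 100 uniform time
  fractions; averaging of trial paths is pointwise in these normalized
  coordinates with t-interval 95 % half-widths over trials or subjects.

## Synthetic experiments

The generator emulates a three-group, 8-subjects-per-group study: 10 blocks
of 48 center-out-and-between reaches among 3 targets (16 per target per
block, randomized order without immediate repeats, chained so each reach
starts at the previous target), 1 s movements with a 0.1 s lead-in and 0.5 s
hold, recorded at 100 Hz. Targets sit on a 0.15 m equilateral triangle
centered 0.30 m in front of the pivot (one vertex toward the pivot),
comfortably inside the 0.4 m reach.

Each trial's spatial path blends the straight segment with the
effort-optimal curved path for its ordered target pair,
w(trial) = w∞(1 − e^{−λ·trial}), traversed with a minimum-jerk speed
profile. Motor noise is a smooth sum of low-order sine modes orthogonal to
the path, anchored to zero at both endpoints; start/end positions scatter
around the target centers (sd 2 mm). Forces are produced by actually
driving the group's haptic object through the spring-damper at 1 kHz.

Group defaults: Group 1 (veridical pendulum vision + haptics) w∞ = 0.9,
λ = 0.004 per trial, σ = 5 mm; Groups 2 and 3 (incongruent feedback;
pendulum and point-mass haptics respectively) w∞ = 0, σ = 4 mm. Per-subject
λ and σ are jittered log-normally (sd 0.15). These values were fixed once so
that the generator reproduces, by construction, the qualitative study
outcome at this geometry's curvature scale (geodesics deviate 7–9 mm in DFD
from the straight paths at 0.15 m separations): gradual divergence of
Group 1 across blocks, incomplete convergence (w∞ < 1), larger Group-1
variability, and group contrasts detectable at n = 8 with p < 0.01. What
the generator does *not* model: arm biomechanics, physiological noise
structure, reaction times, online corrections, or haptic-rendering latency —
so passing tests demonstrate the pipeline's correctness and sensitivity, not
properties of human movement.

## Group statistics

Subject means over the last block are the unit of analysis. A classical
one-way ANOVA (F = MS_between/MS_within) tests the omnibus group effect;
zero within-group variance with unequal means is reported as F = ∞, p = 0
with a degeneracy flag. Many-to-one (Dunnett-style) contrasts compare each
group against Group 1: the family-wise adjustment references the joint null
distribution of max|t| over contrasts, evaluated by Monte Carlo (default
100 000 simulated experiments with the observed group sizes; fewer than
1000 is refused). Monte-Carlo adjusted p-values are clipped into the
provable bracket [unadjusted p, Bonferroni p], inside which the exact
adjusted p always lies; this makes the bracket guarantee exact rather than
subject to simulation error. The implementation is cross-checked against an
independent library Dunnett test in the suite, and its omnibus type-I error
under a null generator (all groups given Group 2's behavior) is verified to
sit in [0.03, 0.07] at α = 0.05 over 1000 reduced-size experiments
(6 subjects per group, one 6-reach block, kinematic trials — sizes chosen to
keep the calibration study itself a routine computation).

## Numerical and design choices, in brief

* Pivot location and target coordinates are not externally constrained;
  only relative geometry matters for every computed quantity, so the pivot
  defaults to the origin with the triangle in front of it (configurable).
* Angles are stored unwrapped; boundary configurations are wrapped to the
  nearest 2π branch of the start configuration before solving.
* Work integrals use trapezoidal quadrature of |F·v| at the recording rate.
* Reference paths are computed once per ordered target pair and memoized,
  optionally to a disk cache keyed by a hash of parameters + layout.
* All randomness flows from explicit `numpy` generators seeded through one
  `SeedSequence` tree; same seed ⇒ bit-identical datasets and CSVs.

## Known limitations

* The geodesic BVP returns the least-energy solution found among its
  multi-starts; global optimality is corroborated (not proven) by the
  independent direct minimizer.
* The effort-optimal solver's mode basis bounds the achievable shapes; with
  the default 6 modes the remaining cost decrease from adding modes is
  negligible for task-scale reaches, but highly contorted optima would need
  a richer basis.
* DFD floors: segmentation clips ~0.6 % of the path length at each end, so
  even perfect reaches carry a ~1 mm DFD offset from the full-span
  references; this offset is common to all groups and cancels in contrasts.
* The ANOVA assumes approximately normal subject means; DFD means are
  mildly skewed, which the null-calibration test shows is immaterial at
  these sizes.
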