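# Methods

## Model

The limb is a pelvis → thigh → shank → foot chain.  The pelvis floats on six
coordinates (three translations, three Cardan Y-X′-Z″ rotations); hip, knee
and ankle each carry up to three rotational degrees of freedom applied in
the same Cardan order (flexion/extension about Y, ad/abduction about X′,
long-axis rotation about Z″).  In the reference pose the limb is fully
straightened with X cranial, Y toward the animal's left and Z vertical; all
joint coordinates are zero there, and extension, abduction and external
rotation are positive.  The knee's flexion axis is −Y so the chain zig-zags
anatomically.  In the nominal configuration the knee and ankle non-sagittal
DOFs are disabled (those joints permit little such motion); a model variant
enables them for the sensitivity analysis.

Segment masses, centres of mass and rod-like inertia tensors are synthetic
but sized for a ~27 kg dog with the hindlimb a few percent of body mass
(thigh 1.30 kg, shank 0.55 kg, foot 0.25 kg); the pelvis segment (12 kg)
stands in for the hindquarter share of the trunk, and whatever it cannot
balance is absorbed by the pelvis residuals, as in any single-limb analysis.
A uniform density of 1060 kg m⁻³ is the bookkeeping assumption behind the
scaling rules: `scale_model` scales geometry linearly, masses by factor³ and
inertia by factor⁵ per segment, with the pelvis factor the arithmetic mean
of the thigh/shank/foot factors.

## Muscle mechanics

Each of the 29 musculotendon units is a rigid-tendon Hill actuator built
from the packaged architecture table (PCSA, pennation at optimal length,
optimal fibre length, tendon slack length; maximal force `PCSA × 300 kN m⁻²`,
with the table's printed forces used verbatim).  Fibre kinematics use the
constant-height construction: `h = l_opt sin α_opt` is fixed, the fibre
projection is `p = L_MTU − L_ts`, `l_fibre = √(h² + p²)`,
`cos α = p / l_fibre`.  If the tendon goes slack (`p ≤ 0`) with nonzero
pennation, the fibre is held at its height with `cos α = 0` (no force
transmission); at zero pennation a slack tendon is an error, surfaced with
the muscle's name.  The active force–length curve is the symmetric parabola
`f_L(l̃) = max(0, 1 − ((l̃−1)/0.5)²)` — the simplest curve that is maximal at
optimum and vanishes at the 0.5/1.5 operating limits.  There is no
force–velocity factor and no passive muscle force: the static optimization
is purely posture-dependent, and the `FibreState` type leaves room to add a
velocity factor later.

Muscle paths are via-point polylines.  Each joint crossing is realised as a
pulley-style pair of points flanking the joint at the lateral offset that
produces the intended moment arm, pre-rotated so the pair is aligned at the
middle of the StS sweep; this keeps arm signs stable across the deeply
folded crouch (joints fold 90–130°), standing in for the wrapping surfaces
and retinacula of an anatomical model.  Moment arms are computed by tendon
excursion, `r = −∂L_MTU/∂θ`, central finite difference with a 1e-4 rad step;
on single-hinge fixtures this agrees with the analytic perpendicular-distance
arm to better than 1e-6 m.

## Calibration

The default model is calibrated deterministically in two stages, mirroring
how a rigid-tendon simulation must be prepared for a movement that spans
most of the joints' ranges:

1. **Standing tendon-slack-length tuning.**  For each muscle, if the
   normalized fibre length in the quiet-standing posture lies outside
   [0.8, 1.2], the tendon slack length is adjusted by bisection (tolerance
   1e-6 cm, ≤200 iterations) until it sits on the nearest boundary.  The
   adjustment is reported as a fraction of MTU length.  The operation is
   idempotent.
2. **Fibre-range retuning.**  If normalized fibre length still leaves
   [0.5, 1.5] anywhere over the default StS sweep, the optimal fibre length
   is increased — and the tendon shortened by the same amount, conserving
   MTU rest length to <1e-9 cm — to the minimal value that keeps the fibre
   inside the admissible band (bisection on feasibility, which is monotone
   in fibre length).  On the default model this retunes mostly the distal,
   short-fibred, long-tendoned muscles (gastrocnemii, deep and superficial
   digital flexors, digital extensors), the same anatomical group a real
   calibration flags.

Architecture is first rescaled to the synthetic path geometry preserving
each muscle's fibre:tendon ratio, so short-fibre/long-tendon character — the
driver of the distal sensitivity results — carries over from the table.

## Experimental-style processing

Markers (180 Hz) are gap-filled (leading gaps take the first valid value,
matching how occluded foot markers behave in the initial crouch; interior
gaps ≤0.1 s are linearly interpolated, longer ones flagged), then low-pass
filtered with a zero-phase 4th-order Butterworth at 6 Hz.  Zero-phase
(forward–backward) filtering is used everywhere so event timing on the %StS
axis is not shifted; the effective attenuation is the squared single-pass
response.  Segment poses come from an orthogonal Procrustes (Kabsch, det +1)
fit of each rigid three-marker cluster against a static standing
calibration; clusters with condition worse than 1e-6 raise a degenerate-
frame error.  Joint angles are Cardan Y-X′-Z″ of the parent-relative
rotation, sign-mapped to extension/abduction/external-rotation positive and
unwrapped; near gimbal lock (|cos θx| < 1e-6) the third angle is zeroed and
the frame flagged — deterministic and loud.  Trials are screened against
the group mean with a 45° maximum-absolute-deviation rule (a cycle-mean mode
is config-exposed, since "differed from the group average" is ambiguous),
time-normalized to a 100-point 0–100 %StS grid by linear interpolation with
exact endpoints, and ensemble-averaged subject-first so unbalanced trial
counts cannot bias the grand mean.

Force-plate records (1800 Hz) are de-meaned against an unloaded baseline
window (default first 0.2 s, config-set — only "de-meaned" is prescribed),
filtered with the same zero-phase 4th-order 6 Hz Butterworth, and decimated
by keeping every 10th sample, in that order.  Both hindfeet share one
plate, so the single-limb wrench halves the vertical and craniocaudal
components and zeroes the mediolateral one (bilateral symmetry).  The
centre of pressure is constrained to the foot midline (midpoints of the
lateral/medial ankle and metatarsal-head markers); frames with vertical
force below 5 N (standard practice) have an undefined CoP.  In the
end-to-end pipeline the CoP rolls from under the hock to under the
metatarsal heads as the foot moves from plantigrade to digitigrade, which
is what produces the large craniad CoP translation over the movement.

## Inverse dynamics

Net generalized forces are computed by the d'Alembert / virtual-work
balance: for each coordinate `j`,

    τ_j = Σ_s [ m_s (a_s − g)·J_v(s,j) + (I_s α_s + ω_s × I_s ω_s)·J_ω(s,j) ]
          − F_grf · J_p(j),

with linear and angular segment Jacobians obtained by central finite
differences of the forward kinematics (step 1e-6) and `J_p` the Jacobian of
the foot material point at the CoP.  For the rotational joint coordinates
this is exactly the net joint moment about that DOF and pairs consistently
with the tendon-excursion moment arms in the optimization; the six pelvis
coordinates yield the residual force and torque.  Joint coordinates are
low-pass filtered (zero-phase 3rd-order Butterworth, 6 Hz — deliberately a
different order from the marker filter, both implemented exactly where they
apply) before differentiation by central differences.  A quasi-static flag
zeroes all velocities and accelerations.

Measured on the default synthetic trial, the quasi-static approximation
agrees with full dynamics to within ~2–6 % RMS at the knee, ankle and
non-sagittal hip DOFs, but differs by roughly a third at hip
flexion/extension: completing a ~53° hip extension within the first fifth
of a 1.14 s movement implies peak angular accelerations of order
100 rad s⁻², a genuinely non-negligible inertial torque.  The movement is
"slow" distally, not at the hip burst; the full-dynamics path is therefore
the default.

## Static optimization

Each frame solves

    min_a Σ a_i² + Σ_j (reserve_j / R₀)²   s.t.  Σ_i r_ij F_i(a_i) + reserve_j = τ_j,
    0 ≤ a_i ≤ 1,

with `F_i(a) = a F_max,i f_L(l̃_i) cos α_i` linear in activation.
Eliminating the reserves turns the problem into a box-constrained linear
least-squares program solved exactly with BVLS; the moment balance then
holds to machine precision by construction, and the strictly convex
objective needs no tie-breaking.  Muscles whose force scale
`f_L · cos α < 1e-9` are excluded from the frame's constraint matrix (they
receive zero activation), keeping the problem well-scaled.  Pelvis residual
coordinates never enter the muscle constraint set.

`R₀` (default 1 Nm, config-exposed) sets how expensive reserves are relative
to muscle effort.  With the default, the reserve term is a soft penalty:
closed-form activation formulas and exact-recovery identities hold in the
stiff-penalty limit, so identifiability checks (square recovery, the
two-muscle Lagrange fixture) run with `R₀ = 0.001 Nm`, where recovery is
exact to ≤1e-6.  Solves are frame-independent (no activation dynamics);
non-converged frames are flagged and more than 5 % flagged frames abort the
run.  Reserves are summarized per DOF as cycle-average and peak absolute
torques with percentages of the corresponding inverse-dynamics torques
(computed from unrounded series), flagged when exceeding 1 Nm or 5 %.
Muscles are reported when peak activation exceeds 0.2 or peak force exceeds
0.2 body weights.

## Sensitivity analyses

Three perturbation families: tendon slack length scaled by ±10 % across all
muscles simultaneously (per-muscle perturbation available for diagnostics);
knee/ankle non-sagittal rotations either zeroed (nominal) or driven by their
measured series with the corresponding DOFs enabled; and a re-run on an
alternative trial (longer duration, trial-specific ranges of motion).
Comparisons report per-muscle percent changes in cycle-average and peak
activation, guarded for baselines below 1e-3 by absolute differences, plus
per-DOF reserve changes.  With a rigid tendon, −10 % slack length shifts
normalized fibre length by `+0.1 · L_ts/l_opt` at fixed MTU length, so
long-tendoned distal muscles (ratios of 10–20) move by whole units of
optimal fibre length — the geometric reason the distal limb dominates the
sensitivity results.  On the default trial, +10 % tendon length reduces the
summed reserve magnitude by roughly a quarter.

## Synthetic trials

The generator emulates the empirical structure of canine StS: monotone
logistic extensions confined to proximal-to-distal timing windows (hip
0–20 %StS, knee 10–50 %, ankle 25–60 %; steepness chosen so the tail rate at
the window edges is ~1 % of peak), ranges of motion of 53.4/78.5/88.7°
ending at quiet-standing angles, small non-sagittal hip bumps, a combined
hindlimb vertical force moving between crouched and standing weight shares
(defaults 0.45/0.55 body weights, config-exposed) with a peak of one body
weight at 20 %StS, a craniad pulse at 15 %StS, a craniad CoP excursion,
trial durations of 1.14 s (jitter SD 0.16 s in the ensemble generator), and
additive Gaussian marker (1 mm) and force (2 N) noise.  The pelvis path pins
the lateral metatarsal head to its initial ground point, so the foot stays
planted while the body rises.  One seed drives all noise; ground truth
(noiseless angles, forces, and generating activations for recovery cases)
is stored alongside the observables, and identical seeds give bit-identical
trials.

What the generator does **not** emulate: soft-tissue artifact (markers are
rigidly attached to segments), rolling/asymmetric StS strategies, forelimb
mechanics beyond a constant support share, anatomical wrap geometry, and
trial-to-trial within-subject correlation structure.  Passing tests
therefore demonstrate that the pipeline's mathematics is correct and
self-consistent — kinematic round trips, moment balance, recovery of known
activations, direction of tendon-slack-length effects — not that its
outputs numerically match any particular animal's measurements.

## Numerical choices

- Finite differences: moment arms 1e-4 rad (central); kinematic Jacobians
  1e-6; time derivatives central with one-sided ends.
- Bisection tolerances: TSL tuning 1e-6 cm (≤200 iterations); fibre
  retuning 1e-9 cm on feasibility.
- Solver: BVLS on the stacked least-squares form; activation bounds
  enforced to 1e-8; balance residual machine-precision by construction.
- Degenerate inputs are loud: slack zero-pennation tendons, collinear
  clusters (condition < 1e-6), gimbal proximity (|cos θx| < 1e-6), CoP
  undefined under load, non-monotone STO time columns all raise typed
  errors naming the offender.
- All angles are degrees at I/O boundaries and radians internally;
  architecture lengths are cm as tabulated, geometry metres.

## Known limitations

Rigid tendons overstate fibre length changes and activation demands —
deliberately, since isolating what fibres alone can do is the point of the
analysis; a compliant-tendon forward simulation would give quantitatively
different answers.  The via-point pulley construction bounds but does not
reproduce anatomical moment-arm profiles.  The default segment inertia and
muscle-path geometry are synthetic stand-ins sized to be realistic, not
measured; conclusions about absolute joint moments should use subject-
specific inputs through the same pipeline.
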