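# Methods

This note documents the models, numerical methods and design choices behind
`gaitopt`, in the spirit of a model-description paper: what is simulated, how
the optimization problems are posed and solved, which parameters matter, and
what the synthetic data do and do not capture.

## 1. Musculoskeletal model

The default model is a bilateral sagittal-plane linkage with nine degrees of
freedom: pelvis translation (x forward, y up), trunk (HAT: head–arms–trunk)
tilt, and hip/knee/ankle pin joints per leg. Hip and knee flexion and ankle
dorsiflexion are positive; radians internally, degrees in all files.

Segment masses and lengths scale from a standard planar anthropometry table
(Winter-style fractions of body mass and height); the HAT segment absorbs
floating-point residue so the segment masses sum to the configured body mass
exactly (checked to 1e−9 kg after every variant operation).

Each leg carries nine Hill-type musculotendon actuators covering the sagittal
functional groups (iliopsoas, gluteus maximus, lumped hamstrings, rectus
femoris, vasti, biceps femoris short head, gastrocnemius, soleus, tibialis
anterior). Path geometry is polynomial per muscle: the moment arm about a
joint is r(q) = r0 + r1·q and the musculotendon length is the exactly
consistent integral, so r = −∂l/∂q holds to machine precision. The generic
parameters (maximal isometric force, optimal fiber length, tendon slack
length, pennation) are literature-scale values stored in the package config;
they are assumptions, clearly marked as such, and fully overridable.

Model variants:

- **Knee disarticulation (amputee).** The ipsilateral (IL) knee becomes the
  microprocessor-controlled prosthetic knee (MPK): a first-order activation
  state `a_MPK` driven by an excitation control, producing a resistive moment
  `T = a_MPK · D_MPK · q̇` (damper coefficient 1.0 N·m·s/rad in the reference
  setting, 0.75 when deactivated), plus an exponential passive moment with a
  hyperextension stop and a flexion limit at 137.5°. The IL ankle becomes a
  passive energy-storage-and-return (ESR) foot: a linear rotational spring
  (300 N·m/rad) with damping, no degree of freedom removed. Only the
  hip-spanning IL muscles are retained, their paths truncated at the hip.
  Prosthetic shank/foot masses default to 60% of the intact segments (the
  device masses are not publicly specified; this is an assumption exposed in
  config). A convenience builder back-computes the intact base mass so the
  amputee model hits a target total mass exactly.
- **Hypothetical healthy twin.** The contralateral (CL) side is mirrored over
  the IL side, the prosthesis removed, and the total mass raised to the
  prescribed healthy mass by uniform scaling (intact limbs outweigh the
  prosthesis).
- **Stiff-knee gait (SKG).** The IL knee (or MPK) passive flexion limit is
  reduced (14.9°, 30°, 35° conditions); the orthosis variant additionally
  adds the brace masses to the IL thigh and shank and limits flexion to 20°.

## 2. Continuous-time dynamics

All physics is C¹-smooth and written against a small vectorized forward-mode
automatic-differentiation layer, so every residual offers exact first
derivatives at every collocation point.

- **Hill muscle.** Implicit (tendon-force-state) formulation: the states are
  activation a and tendon force normalized by maximal isometric force; their
  time derivatives are controls. The tendon force–length curve is exponential
  with 4.9% strain at maximal isometric force and zero force at slack length
  (which makes the slack equilibrium exact); active force–length is Gaussian
  (width 0.45); force–velocity is a smooth logistic Hill shape with value 1
  at zero velocity, ≈0 at −v_max and an eccentric plateau of 1.4; constant-
  width pennation; a small normalized fiber damping (0.01) regularizes the
  force–velocity inversion. The equilibrium residual is strictly decreasing
  in the tendon-force state, so a bisection bracket [0, 3] always contains
  exactly one static solution — this bisection solver seeds the optimization
  but never replaces the implicit dynamics.
- **Activation dynamics.** First-order excitation–activation dynamics with
  τ_act = 15 ms and τ_deact = 60 ms, blended by a steep logistic in (e − a).
  Inside the collocated problems the excitation is eliminated: the activation
  rate control is bounded by the linear inequalities
  τ_act·ȧ ≤ 1 − a and −a ≤ τ_deact·ȧ, which is the same feasible set and
  keeps the constraints linear. The MPK activation uses a plain first-order
  lag (τ = 30 ms).
- **Passive joint moments.** Double-exponential limit moments plus linear
  damping and an optional linear spring (used by the ESR ankle). The SKG
  conditions simply move the flexion limit angle.
- **Contact.** Hunt–Crossley spheres (heel and toe per foot) on the plane
  y = 0: normal force k·δ^1.5·(1 + 1.5·c·δ̇), penetration smoothed by a
  softplus of scale 1e−4 m and the dissipation bracket smoothly clamped
  nonnegative (no adhesion under any separation velocity); tangential force
  is smoothed Coulomb friction with the friction moment of the contact
  offset. The default stiffness is 2·10⁵ N·m^−1.5, giving ≈1.5 cm static
  penetration under body weight — deliberately compliant: it keeps the
  desk-scale collocation problems well-conditioned while preserving the
  double-bump loading pattern.
- **Metabolic rate.** A smooth Bhargava-style surrogate: activation/
  maintenance heat proportional to activation, shortening heat proportional
  to activation times the positive shortening speed, positive mechanical
  fiber work, all positive parts via softplus (scale 0.1 W), scaled by a
  muscle mass estimated from maximal isometric force and optimal fiber
  length (specific tension 0.25 MPa), plus a whole-body basal rate
  (1.2 W/kg).
- **Equations of motion.** The planar tree's implicit EOM residual is
  evaluated by generalized inverse dynamics via virtual work (per-segment
  COM accelerations dotted with analytically known Jacobian rows), which is
  exact for this topology and cheap to differentiate. The residual is scaled
  by 1/(m·g) inside the optimization.

## 3. Optimal-control problems

Both problems use third-order Radau (IIA) direct collocation: states are
degree-3 Lagrange polynomials per mesh interval, dynamics are enforced at the
three Radau nodes (which include the interval end, making mesh continuity
implicit), and the state-derivative controls are resolved **at the
collocation nodes** — with interval-constant derivative controls the implicit
Hill/EOM path constraints would overdetermine the system by one equation per
muscle and interval.

**Parameter estimation.** Reproduces a hip joint-moment trajectory with the
IL hip muscles while scaling each muscle's maximal isometric force, optimal
fiber length and tendon slack length within [50%, 200%] of generic. The
objective integrates activations squared, optimal fiber length, reserve
actuator squared and squared state derivatives. Weights (10, 1 m⁻¹, 0.1,
1e−3): because the tendon force is normalized here, the published-scale
derivative weight would dwarf the reserve penalty and park tens of N·m on
the reserves; the chosen pair restores the intended hierarchy (reserves
≪1 N·m RMS on generic-feasible data). *Known identifiability limit:* the
effort objective decreases monotonically in every strength multiplier
(activation ∼ 1/f_max at matched moments), so without passive-force
counter-pressure the strength estimates drift to the upper bound; strength is
pinned from below by demand near capacity but not from above. Recovery tests
therefore assert movement toward the truth and improved fit, not a two-sided
window. Optimal fiber length and tendon slack length share a sloppy direction
(shorter fibers compensated by longer tendons) that the fiber-length penalty
exploits; this is reported as-is.

**Predictive gait.** Minimizes the integral of
w₁·Σa² + w₂·Ė² + w₃·Σq̈² + w₄·Σ(ȧ² + Ḟ̃²) + w₅·e_MPK²
divided by the distance traveled by the pelvis, subject to the full implicit
dynamics, periodicity of all states except the pelvis forward position, and
an imposed average speed with the cycle time T free (the distance equals
speed × T through the constraint, and that product is used as the
denominator so it stays positive far from feasibility). Default weights
(100, 1e−4 W⁻², 0.01 rad⁻²s⁴, 0.05, 1) balance the terms to the same order
of magnitude on the nominal guess. The cycle time is bounded to [0.8, 1.5] s,
a cadence window bracketing observed walking at ≈1.5 m/s that also excludes a
degenerate fast-stepping local basin. The objective is normalized by its
value at the initial guess, which conditions the solver and makes a common
rescaling of all weights cancel exactly.

The initial guess is built from the synthetic nominal gait templates
(kinematics with the contralateral side phase-shifted half a cycle, pelvis
height set to the static contact-balance penetration, velocities and
accelerations from periodic splines, muscle states at activation 0.1 with
tendon forces at static equilibrium). A guess can also come from a trial file
or a prior solution; a multistart helper perturbs the guess smoothly and
reports every objective (local minima are expected and real — different
basins differ by a few degrees in peak kinematics).

## 4. NLP solver

The transcribed problems are solved by a safeguarded augmented-Lagrangian
method with projected-Newton inner solves:

- exact sparse constraint Jacobians are assembled from the AD layer (dense
  per-node blocks plus analytic collocation/periodicity/speed entries);
- the inner model Hessian is Gauss–Newton, μ·JᵀJ plus the diagonal
  Gauss–Newton curvature of the objective and an adaptive Levenberg damping;
  steps come from a sparse KKT factorization (SuperLU, minimum-degree
  ordering), with the structurally dense free-cycle-time column eliminated by
  a rank-one Schur complement and factorizations reused for a few chord
  steps;
- multipliers follow first-order updates accepted on sufficient feasibility
  progress, the penalty grows moderately when feasibility stalls, and the
  inner stationarity tolerance tightens as the multipliers converge;
- the predictive problem uses one contact-stiffness continuation stage
  (ground softened to 3·10⁴ N·m^−1.5, solved loosely, then the full model
  warm-started with the pelvis raised by the static penetration difference):
  the contact force is the one severely non-quadratic term, and without the
  homotopy the line searches crawl;
- condition variants (altered damping, SKG limits) are re-solved warm-started
  from the reference solution — primal variables and multipliers — which is
  both faster and keeps between-condition comparisons within one basin
  (tightening SKG limits are chained in sequence).

Convergence is declared at a scaled feasibility of 1e−6 with the objective
settled between multiplier updates; a feasible point whose objective is still
drifting at the iteration cap is reported as converged with an explanatory
message, and every returned solution is re-verified post hoc by independently
re-evaluating all residuals at the collocation points. Non-convergence never
raises: the trajectories are returned with diagnostic statistics.

## 5. Problem sizes

The package defaults are desk-scale: estimation uses 12–20 mesh intervals
(a ~1500-variable NLP, seconds to tens of seconds), predictions use 8–16
intervals (≈2500–4800 variables, one to a few minutes cold, faster warm).
The acceptance script solves the reference prediction at 16 intervals and
the statistics target with 1000 Monte-Carlo repetitions. Larger meshes are a
config switch; accuracy grows at the collocation order (observed ≥ 5th-order
endpoint convergence on smooth test dynamics).

## 6. Synthetic data

The generator emulates the study conditions without any external download:
periodic gait curves on the canonical 101-sample cycle built from sums of
wrapped Gaussians (double-peaked knee flexion with a ≈65° swing peak,
double-bump vertical ground reaction force, burst-like EMG envelopes),
5 repeated trials for amputee-like and 7 for healthy-like protocols, with
multiplicative amplitude variability (SD 5%) and a smooth periodic time warp
(SD 1% cycle); kinematics carry no additive white noise (non-physiological),
EMG envelopes optionally do. Stiff-knee phenotypes saturate the knee curve
smoothly below the restriction (idempotent up to the 0.4° smoothing margin)
and add the contralateral early-stance knee-moment compensation.

Estimation datasets are built to be *exactly* achievable: tendon-force
trajectories come from pointwise static equilibrium under smooth target
activation profiles, are differentiated with periodic splines, and the
activations are then back-solved from the implicit Hill residual (which is
affine in activation), so the stored truth satisfies the dynamics to machine
precision and the moments are reproducible with zero reserves. The drive
peak is configurable; near-maximal drive (0.9) is used when strength
identifiability matters.

Every dataset ships its generating truth; tests only compare against stored
truth or analytic values.

What passing tests on these data do **not** show: the templates are
qualitative normative shapes, not subject data; the trial-to-trial
variability model has no inter-stride correlation structure, no soft-tissue
artifact, and no EMG crosstalk; and the reduced planar model cannot express
frontal/transverse-plane compensations, so agreement here does not imply
agreement with three-dimensional experimental gait.

## 7. Statistics

The nonparametric 1D SPM paired test builds the null distribution of the
curve maximum of |t| from sign flips of the trial differences — exhaustive
up to 2^13, otherwise a seeded subsample of 10,000 patterns including the
identity; the critical threshold is the (1−α) quantile (method "higher"),
inference is two-tailed on |t|, and nodes with identically zero differences
get t = 0. With 7 trials (128 permutations) the attainable family-wise rate
at α = 0.05 is 6/128 ≈ 4.7%, within the Monte-Carlo band of the nominal
level. A resolution warning fires when 2ⁿ·α < 1.

DTW uses the standard dynamic program with a Sakoe–Chiba band of half-width
ceil(0.05·N) (5% maximal shift), endpoints pinned, cost equal to the total
accumulated |difference| along the optimal path (per-step normalization is
not applied; the identity score is exactly zero either way). Curves entering
a comparison are first divided by the maximum absolute value over that
comparison's curve set (normalization constant per comparison, not global),
mapping them into [−1, 1]. Grouped-muscle curves are pointwise maxima of
their components; muscles absent on one side yield NaN entries in the score
matrix, never numeric overflow. Peak metrics refine the discrete argmax with
a parabola through its neighbors, ties breaking toward the earlier sample.

## 8. Known limitations

- Planar model: no frontal/transverse degrees of freedom, two contact
  spheres per foot, lumped muscle groups; headline angles are reduced-model
  quantities, not subject-specific predictions.
- The gait predictions are local optima; different guesses give slightly
  different gaits (reported, not hidden). Between-condition effects are
  therefore always evaluated on warm-started chains.
- Compliant ground (≈1.5 cm static penetration) trades contact realism for
  robust desk-scale convergence.
- Strength parameters are upper-bound-unidentifiable from moments alone
  under an effort objective (see §3).
- The MPK damping law is the printed bilinear form; the real
  magnetorheological device is state-dependent in richer ways.
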