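# Methods

`neuromusc` simulates lower-limb strength and plyometric training tasks
with a reduced sagittal-plane musculoskeletal model, resolves muscle
redundancy by frame-wise static optimization, derives neuromuscular
metrics and adaptation proxies from the simulated mechanics, quantifies
their robustness and uncertainty, and trains regression models that map
simulation features to a composite adaptation score. Everything in the
pipeline is synthetic and deterministic given a seed; the purpose is
hypothesis generation and method development, not subject-level
prediction.

## Body model

The body is a planar chain of four rigid segments — foot, shank, thigh
and a lumped head–arms–trunk (HAT) segment — articulated at the ankle,
knee and hip. The model is bilaterally symmetric: both legs move
identically, the leg segments carry the mass of both legs, and reported
joint moments are per-leg values (half of the chain totals). Segment
mass and length fractions, COM offsets and radii of gyration follow
standard cadaver-based anthropometric tables; the default athlete is
1.80 m and 75 kg and any other athlete is produced by proportional
scaling (lengths with the height ratio, masses with the mass ratio,
inertias with mass × length², muscle forces with mass, muscle lengths
with height). Scaling is exactly compositional.

Joint coordinates are hip flexion, knee flexion, and ankle dorsiflexion
(radians internally); torques are reported extension/plantarflexion
positive. Inverse dynamics is a bottom-up planar Newton–Euler recursion
from the measured ground reaction force (GRF) and centre of pressure
through foot, shank and thigh; closing the recursion at the HAT yields a
residual force that is zero for dynamically consistent inputs and serves
as the pipeline's consistency audit.

## Muscles

Eight muscle-tendon groups per leg span the three joints: gluteus
maximus, iliopsoas, hamstrings, rectus femoris, vasti, gastrocnemius,
soleus and tibialis anterior. Each is a Hill-type actuator:

* active force–length: Gaussian `exp(−(l̃−1)²/0.45)`;
* force–velocity: Hill hyperbola with shape 0.25 concentric and a
  smooth, slope-matched exponential eccentric branch with plateau 1.4;
* passive force–length: exponential, zero at or below optimal length and
  normalised to 1 at 60% strain;
* tendon: linear above slack with normalised stiffness k_T = 35 (force
  fraction of F_max per unit strain);
* pennation: constant-thickness rule `l_m sin α = l_opt sin α₀`, cos α
  floored at 0.1;
* maximal shortening velocity 10 optimal fiber lengths per second.

All shapes are config-overridable. The parameter table (maximal
isometric forces, optimal fiber lengths, tendon slack lengths, pennation
angles) contains literature-plausible group-level values and ships as a
versioned YAML file; no published parameter set exists for this reduced
model, so the table is owned by this package. Moment arms are constant
per muscle–joint pair (2–6 cm, signed), which makes musculotendon length
affine in the joint angles; the reference posture at which every fiber
sits at optimal length is placed mid-range of the task repertoire
(hip 45°, knee 60°, ankle 10°) so active force–length values stay in a
physiological operating band across all tasks.

Fiber–tendon equilibrium `F_fiber cos α = F_tendon` is solved by bracketed
root finding in fiber length ([0.2, 1.8] l_opt, residual ≤ 10⁻⁶ F_max),
with fiber velocity from a backward difference of fiber length. The
rigid-tendon limit (`l_m = sqrt((l_mt − l_slack)² + h²)`) is used for
per-frame optimization kinematics and is the convergence point of the
elastic solution as stiffness grows.

## Task generation

Seven tasks ship by default: countermovement jump (CMJ), standing broad
jump, drop jumps from 30 cm and 50 cm, back squat, deadlift and leg
press. Plyometric trials last 3 s at 1000 Hz, strength repetitions 4 s
at 1000 Hz (2 s eccentric + 2 s concentric, no pause); each task runs
10 replicates.

Trials are built from a one-parameter posture path — a straight line in
joint space from a stance posture to the task's bottom posture — plus a
whole-body lean (rotation about the ankle). During ground contact the
whole-body COM is prescribed as a piecewise-polynomial trajectory
(quintic or higher, with position, velocity, acceleration and — at
boundaries adjoining ballistic flight — jerk matched), and the path
parameter and lean are solved per frame with a damped Newton iteration
so the chain's COM follows the prescription exactly. Flight phases are
exactly ballistic; airborne joint angles follow a stop–hold–re-enter
profile (knee and ankle in joint space with anatomical floors, the trunk
as its slowly-varying absolute lean angle, hip recovered from the
three), which keeps swing-phase joint moments physiological while
matching position and velocity at both contact boundaries.

The GRF is computed from COM dynamics (`F = M(a_com − g)` plus the
supported external load) with the same finite-difference operator used
by inverse dynamics, so generated trials are dynamically consistent by
construction: the maximal residual trunk force over the default 70
trials is ≈0.33% of body weight (audited in the tests; the acceptance
bound is 0.5%). The centre of pressure is placed mid-foot for lifts and
ramps toward the forefoot during jump push-offs. Phase durations are
quantized to a 2 ms grid so regenerating a trial at any sampling step in
{0.5, 1, 2} ms reproduces identical phase boundaries (this is what makes
the numerical-convergence audit meaningful).

Key kinematic settings and their rationale:

* take-off occurs slightly flexed (12% of the stance→bottom line, knee
  ≈24°) — the COM-height inversion is singular at full extension, and
  real take-offs retain comparable flexion;
* take-off velocities are modest (1.35–2.0 m/s vertical; broad jump
  0.75 m/s forward), representing controlled sub-maximal efforts whose
  moment demands stay within the muscle set's capacity;
* drop-jump amortization has a fixed nominal duration (110 ms, jittered)
  — contact time is a property of leg stiffness, not of drop height, so
  the 50 cm drop decelerates harder over the same interval, which is
  what produces its higher peak GRF and RFD;
* landings are absorbed to a deep catch posture (85% of the path) over
  a velocity-scaled interval;
* the broad jump plants its feet where the COM will come to rest, so it
  lands leaning backward and rides forward over the foot, as long-jump
  landings do.

Replicate perturbations: initial joint angles ±2° (uniform), phase
timings ±5%, and a ±5% jitter on the optimizer's initial activation
guess (the last has no effect on the solutions because the per-frame
problem is convex and solved to optimality; it is retained for interface
completeness). A (task, replicate, seed) triple fully determines a
trial; per-trial child seeds are derived from a CRC of the task name, so
the mapping is stable across runs and platforms.

Strength loading: the maximal feasible joint moments ("1RM" reference)
are computed at task-specific reference postures with prime movers at
full activation and antagonists at 0.05, solving the static
musculotendon equilibrium and summing tendon-force contributions through
the moment-arm matrix. The external resistance is a vertical force on
the HAT segment with line of action through the mid-foot, sized so the
peak per-leg moment demand at the governing joint equals the load
fraction (default 85%) of the reference moment. In this planar geometry
the hip lies far behind the mid-foot load line at the bottom of every
lift while the knee lies nearly on it, so the hip is the load-governing
joint for all three lifts; targeting the knee would require implausible
loads and infeasible hip demands. The default study runs each strength
task at a single load so the bundle is exactly 7 × 10 = 70 trials; both
75% and 85% are available in configuration.

## Static optimization

Each frame minimizes `Σ wᵢ aᵢ² + w_res Σ τ_res²` subject to
`R(q)ᵀ f_m(a, l_m, v_m) + τ_res = τ_ID` and `0 ≤ aᵢ ≤ 1`, with muscle
weights wᵢ = 1 and a heavy reserve penalty w_res = 1000 (both
configurable). Under rigid-tendon per-frame kinematics the musculotendon
force is affine in activation, so the penalty problem is exactly a
bounded linear least-squares problem, solved with a bounded-variable
least-squares routine to KKT stationarity ≤ 10⁻⁶. Reserve torques are
the residual of the equilibrium constraint and are reported always. An
elastic-tendon mode fixed-point iterates the fiber kinematics with the
activation solve (≤5 passes).

Frames are solved every 10 ms and linearly interpolated to the trace
grid — activation waveforms in these tasks are band-limited far below
50 Hz, so decimation does not change any derived metric (the convergence
audit, which also tightens the solver tolerance, confirms ≲0.1%
differences). Only stance frames are solved; airborne frames carry zero
activation, because swing-phase moment demands in the reduced planar
model reflect the airborne interpolation rather than muscular effort.
A trial is marked invalid if more than 1% of solved frames fail to
converge (none do under the defaults). On all default tasks the mean
absolute reserve torque is below 1% of the peak moment demand per joint.

The test oracle enumerates the activation box exhaustively (≤3 muscles),
keeps points whose equilibrium residual is within a grid-consistent
tolerance, and returns the minimal-effort feasible point (or the
minimal-penalty point when the demand exceeds capacity). For problems
with two incommensurate agonists at one joint the effort surface is
nearly flat along the torque-trade direction and the grid cannot track
the constraint manifold, so activation-level agreement with the
continuous solver is only guaranteed for non-degenerate problems
(distinct joints, or grid-commensurate capacities); the degenerate case
is checked at the level of effort and reconstructed torque.

## Metrics and adaptation proxies

Per trial: peak vertical GRF (N/kg), rate of force development (RFD:
ΔF/Δt of vertical GRF over 0–100 ms from force onset; the trial value is
the steepest rise over all onsets), loading rate (peak 10 ms moving
slope in the first 100 ms after onset), net vertical impulse, stance
peak joint moments and extensor moment impulses per joint (per leg,
N·m/kg and N·m·s), time to peak moment, propulsion-phase peak hip/knee
moment, peak joint power, peak activations, activation-synchrony index
(mean pairwise Pearson correlation of the six prime movers over the main
effort window, resampled to 101 points), contact and amortization times.
Force onset is the first interpolated upward crossing of 5% body weight
after an unloaded phase; traces that never unload (lifts) fall back to
the sub-sample-interpolated force minimum, which keeps the estimate
continuous in the sampling step.

Waveform variability across replicates is the mean point-wise
coefficient of variation of time-normalized (101-point) waveforms, in
percent.

Adaptation proxies are z-scored across the task × load ensemble:
maximal strength (peak dominant-joint moment + moment impulse),
explosive (RFD and negated time-to-peak), tendon/stretch-shortening
(peak ankle moment + loading rate), coordination (synchrony). Each proxy
is the mean of its z-scored constituents; the composite adaptation score
is the mean of the four proxies.

Uncertainty: point estimates are medians over replicates; intervals are
bias-corrected and accelerated (BCa) bootstrap 95% intervals (default
B = 200; bias correction from the bootstrap fraction below the point
estimate, acceleration from jackknife skewness); effect sizes are
standardized mean differences (median − baseline)/s with s the
replicate SD, switched to MAD × 1.4826 when |adjusted Fisher–Pearson
skewness| > 1. The baseline scenario is configurable and defaults to an
unloaded quiet-stance trial.

## Sensitivity and robustness

Perturbation families (shipped ranges): muscle F_max ±10%, optimal fiber
length ±5%, tendon slack length ±5%, tendon stiffness 0.5–2× (sampled
log-uniformly; all ± ranges uniformly), foot–ground contact stiffness
±25% (amortization compliance scales with 1/√k), anthropometry ±5%, and
zero-mean GRF noise up to ±3% applied before inverse dynamics.
Multipliers act per family (one common multiplier across muscles), which
keeps a 200-draw design informative; a per-muscle mode is available
through the API. One-at-a-time sweeps evaluate each parameter at
{lo, baseline, hi}; the Latin-hypercube design (scipy's sampler, one
draw per marginal stratum) drives standardized-coefficient regressions;
tornado rankings order parameters by maximal absolute relative
deviation (OAT) or standardized-coefficient magnitude (LHS). Failed
re-simulations are recorded as missing, never fatal.

The quasi-static pipeline has no ODE integrator; the "integrator
settings" of the convergence audit map to the trace sampling step
(Δt ∈ {0.5, 1, 2} ms) and the per-frame solver tolerance
({10⁻⁴, 10⁻⁵, 10⁻⁶}). Refining from the baseline (1 ms, 10⁻⁵) to the
finest setting changes RFD, peak moments and synchrony by less than
0.1%; coarsening changes them by a few tenths of a percent.

## Prediction layer

Each solved trial becomes one feature row: metric scalars plus
peak/mean/integral summaries of the time-normalized (101-point) stance
waveforms of the three joint moments, both GRF components and all eight
activations (~55 features for 70 rows). Features are standardized with
training-row statistics; the default target is the composite adaptation
score plus Gaussian noise with SD equal to 10% of the signal SD.

Splits are 70/15/15 train/validation/test, stratified by task × load
with the odd remainder row alternating between validation and test so
global proportions stay balanced. Models — elastic net, RBF-kernel SVR,
random forest, histogram gradient boosting (early stopping on a 10%
inner split, patience 50) and a 3 × 64-unit ReLU multilayer perceptron
(Adam, learning rate 0.001, early stopping) — are tuned by randomized
search (default 200 trials; the acceptance run uses a scaled budget of
20) with 5-fold cross-validation scored by mean absolute error, ties
broken by the lower across-fold SD; a compact grid-search dialect
(learning rates {0.001, 0.005, 0.01}, hidden units {32, 64, 128}, tree
counts {50, 100, 150}) is also available. Feature scaling and optional
PCA (retaining ≥95% training variance) live inside the model pipeline
and are re-fitted within each fold. Reported: per-fold MAE/RMSE/R²
(mean ± SD), held-out test metrics, impurity importances (per-fold,
normalized to 100, fold-median point estimates, BCa intervals over
resampled folds) with permutation importances (10 repeats on a 20%
in-fold validation split) as the robustness check, and residual
diagnostics (calibration intercept/slope, decile bias/MAE, Spearman
ρ(|e|, ŷ), Breusch–Pagan test, residual/Q-Q/calibration plots).

## What the generator does and does not emulate

The generator reproduces the structure of real training data — phase
composition, smooth kinematics meeting published-style angle and timing
targets, dynamically consistent GRF, replicate-level variability, and
realistic orderings across tasks (higher drops give higher impact forces
and RFD; heavy lifts give the highest stance extensor moments). It does
not emulate: three-dimensional or asymmetric motion, heel rise/foot
rollover (the foot stays flat; push-off is represented by the CoP
dialect), proximal-to-distal joint sequencing, arm swing, soft-tissue
and contact transients (impact GRF peaks are smooth rather than
oscillatory), muscle activation dynamics (activations are quasi-static
optimum solutions), fatigue, or inter-subject biological variance.
Passing tests therefore demonstrate internal consistency and correct
method implementation, not fidelity to any experimental dataset; the
prediction-layer accuracy reflects a target built from the same
simulation's proxies and should be read as a pipeline property.

## Numerical choices and problem sizes

Equilibrium root finding: Brent's method, bracket [0.2, 1.8] l_opt.
COM tracking: vectorized damped Newton, tolerance 10⁻¹⁰ m, step cap 0.2.
Per-frame solver: bounded-variable least squares, tolerance 10⁻¹⁰.
Tie-breaks are deterministic (convex problems, deterministic solver).
Default study size: 7 tasks × 10 replicates at 1000 Hz; the acceptance
run additionally uses 100 solver-oracle problems, 50 random static
postures, 500 bootstrap-coverage simulations (n = 30, B = 999), 40
seeded Latin-hypercube runs of 200 draws on the fast maximal-moment
outcome, and the two-task convergence grid. Degenerate inputs (constant
activation traces, zero-variance proxies, degenerate bootstrap
distributions, unloaded force traces) are handled explicitly with
warnings rather than silent propagation.

## Known limitations

* The muscle parameter table and moment arms are plausible defaults, not
  fitted values; absolute moment and force magnitudes should be compared
  across conditions within the model, not against instrumented data.
* The mid-foot load line plus planar geometry makes the hip the
  load-limited joint for all lifts; knee-dominant machines (leg press)
  are represented only through their posture.
* Free moments are not audited: the COM-consistency guarantee covers
  forces; the prescribed CoP dialect can imply a net free moment at the
  base, which is unmodelled.
* Swing-phase joint moments are interpolation artifacts and are excluded
  from metrics and muscle solving by design.
* The composite adaptation target is simulation-derived; models trained
  on it cannot validate against real adaptation outcomes.
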