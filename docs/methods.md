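# Methods

This note records the modeling and numerical choices behind `vtemaze`:
what is simulated, which parameters matter, where the design was genuinely
open, and what the tests do and do not establish.

## World model

The maze is two axis-aligned corridors: a central arm (default 120 × 40 cm)
and a cross corridor (two 120 × 40 cm arms) forming the T. The coordinate
origin sits at the junction center, +y toward the cross arm, headings CCW
from +x. The reward and punishment zones are the distal 10 cm slabs of the
two cross arms; the robot body is a 3.7 cm-radius disc with a 5.3 cm axle
(e-puck scale). The corridor width (40 cm) is chosen against the 20 cm
whisker length: whiskers reach the cue post only when the robot is near
the junction corner, not from anywhere in the corridor. The start pose
defaults to the central-arm centerline, 10 cm from the closed end, facing
the junction. All geometry is configurable.

Kinematics are explicit Euler at 1 step = 1 time unit. For constant u the
integrator traces an exact regular polygon whose circumradius differs from
the analytic arc radius `V·axle/(2c(2u−1))` by O((ω·dt)²); the kinematics
tests assert exactly that bound and that the error shrinks with the step
size. Collisions during maze solving cancel the motion component into the
wall (axis-aligned walls make the axis decomposition exact) and always
allow rotation; trials do not end on contact. During familiarization,
contact instead ends the episode and resets the robot — that phase's
protocol. A trial ends at the first entry of the body center into a reward
or punishment zone, or at the 4000-step budget, and the three outcomes are
mutually exclusive by construction.

Sensors are noise-free and total on valid poses:

* **Whiskers** — 16 per side, fanned 20°–160° from the heading, root on
  the body surface, length 20 cm; a whisker reads 1 iff its segment
  intersects the 2 cm cue post. The post is placed at the junction corner
  on the cued side; it is transparent to the camera and intangible to the
  body (it sits in the wall corner, where the body cannot reach anyway).
* **Camera** — 20 pixels of 18° each, panorama relative to the heading.
  Only the back wall of the cross corridor (the full top of the T) renders
  as 1; everything else is white. A pixel is 1 iff *any* bearing in its bin
  sees the black wall first. Rendering is interval-exact: the first-hit
  wall can change only at wall-vertex bearings, so one ray per sub-interval
  between critical bearings (vertices ∪ bin edges) decides every pixel
  without sampling error. The tests compare against a dense brute-force
  caster that adds rays bracketing each vertex bearing, so sliver arcs
  narrower than the ray spacing are still caught.
* **IR** — six rays at ±15°, ±45°, ±75°, reading `k_IR·max(0, 1 − d/10 cm)`
  of the body-surface-to-wall distance, `k_IR = 1` fixed.
* **Reward channel** — +1 / −1 inside the reward / punishment zone, else 0.

## Controller

Five modules (tactile 32, vision 20, IR 6, reward 1, motor 1), each neuron
a (state, virtual) pair. The state pathway drives plasticity; the virtual
pathway drives behavior; the separation prevents the runaway feedback of
naive Hebbian loops in which firing strengthens the very weights that
cause firing. Per neural step (every δ environment steps, order fixed):
set states → Hebbian update → virtual update → emit u.

The two update rules are the package's concrete rendering of the
Bovet–Pfeifer two-pathway architecture this model builds on:
outer-product potentiation by (postsynaptic state *change*) × (presynaptic
state) with linear forgetting, and sigmoid propagation of the mismatch
e = v − s. Both live behind single functions (`hebbian_update`,
`virtual_update`) so alternative forms can be swapped in. Consequences
worth knowing:

* With a clamped motor (familiarization) the motor state never changes
  within an episode, so weights *into* the motor module stay zero during
  familiarization; the sensorimotor couplings that do form are those with
  changing postsynaptic sensory states (e.g. motor→IR as the robot
  approaches walls). Weights into the motor form during maze solving,
  when u fluctuates.
* Virtual units and the held motor output persist across trials within a
  phase (they reset only at phase starts, as does the weight matrix), so
  consecutive trials of a frozen controller share outcomes but not exact
  trajectories.
* The sigmoid is evaluated with `scipy.special.expit`; under extreme
  weights it saturates to exactly 0.0/1.0 in float64, so the code treats
  u ∈ [0, 1] closed even though the map is mathematically open.

Parameter defaults (all configurable, all serialized into every config):
δ ∈ [10, 30] env steps; τ (delayed-state lag) in *neural* steps, range
[1, 5] — the state change entering the Hebbian rule should be measured at
the controller's own cadence; one shared sigmoid slope a ∈ [0.1, 10]
(a single slope is what makes the 49-parameter count come out); motor
conversion c per phase and forward speed V in [0.1, 5] cm/step; input
gains k_light, k_touch, k_reward in [0.1, 5]. Incoming virtual sums are
plain (un-normalized) by default; a 1/size_j normalization is a switch —
the evolved gains absorb scale either way. Self-pairs carry no weights
(required for 20 directed pairs × 2 rates = 40 rate genes).

## Genetic algorithm

Genomes are [0, 1]⁴⁹ with fixed affine decode maps (rates in [0, 1],
integer rounding for δ and τ). Tournament size defaults to 3; mutation is
per-gene uniform redraw at 1%; crossover single-point at 70%; 5 elites are
copied unmutated. Fitness is a per-outcome reward table (reward = +5,
punishment = timeout = 0) summed over 100 trials from the fixed start —
the minimal table consistent with a printed maximum of 500. On a separable
toy objective (sum of genes, population 50) this operator set reaches
≥ 95% of the optimum by generation 200 and ≥ 99% by about generation 800;
uniform-redraw mutation polishes the final percent slowly, which is a
property of the operators, not a bug.

## VTE detection and suppression

The robot has no independent head, so VTE is read from the signed motor
output m = 2u − 1. The default detector is a Schmitt trigger: an event
requires crossing from beyond +θ to beyond −θ (or vice versa) since the
last event, which filters oscillations inside the band around straight
travel. θ defaults to 0.1 and is always reported next to counts. A
per-step rule (sign change with |Δm| > 2θ) is available behind
`rule="delta"`. Counts are invariant to uniform time-rescaling and
non-increasing in θ; the tests check equivalence against an independent
compress-and-count oracle on random series.

Suppression runs the detector online during a session and overrides u to
0.5 (zero angular velocity) for the neural step of each would-be event;
learning sees the overridden motor state. θ = 1 never fires (|m| < 1) and
is bit-exact identical to an unsuppressed session; θ = 0 blocks every sign
change. Blocked-event totals are a separate quantity from unsuppressed
counts: a blocked crossing leaves the hysteresis side unchanged, so
repeated attempts are each blocked again.

The HL / L / H per-trial profile labels are plumbing, not a result:
by-eye classification of count profiles is replaced by a documented
heuristic (HL if the first-20-trial mean is ≥ 2× the post-50 mean with an
early peak ≥ 2; L if the overall mean < 2; H otherwise), and the label is
always accompanied by the three summary means.

## Lyapunov estimation

Rosenstein small-data method: delay embedding (defaults m = 5, J = 1),
nearest neighbors constrained to temporal separation greater than the mean
period — the reciprocal of the power-weighted mean FFT frequency by
default, the dominant-peak period behind a switch — and a least-squares
fit to the first `fit_len = 10` points of the pair-averaged log-divergence
curve. Gates: a fit is adopted only when R² > 0.8, otherwise the reported
exponent is 0.0; negative slopes (convergence of an already-settled orbit)
also report 0.0. Degenerate pairs (zero initial distance) are excluded,
with a floor of machine-epsilon × series range inside the log; an
all-degenerate series yields a rejected estimate rather than an error.
Series too short for the embedding raise a precondition error from
`mle_rosenstein` but contribute a rejected 0.0 inside `session_mle`.

Calibration: on the r = 4 logistic map (exact exponent ln 2 ≈ 0.6931) the
estimator lands within 0.05 on 5000-point series and stays in a broad
positive band on 150-point series, the length regime of per-trial neural
logs (15–150 neural steps), where the estimate is read as *transient*
chaos. Estimates are exactly invariant under affine rescaling of the
series. Module series are the motor virtual unit (the motor command
itself) and, for sensory modules, the within-module mean of v − s — the
mismatch signal that actually propagates toward the motor. The tests also
check that the *ranking* of module exponents (chaotic vs periodic
channels) survives perturbing (m, J), which is the robustness property
that matters at these series lengths.

## Perturbation experiments

The robustness grid places 7 lateral × 40 longitudinal = 280 start
positions uniformly in the central arm (a margin of body radius + 0.5 cm
keeps poses legal) and runs a fresh familiarization-plus-session per
position — the perturbation applies to the whole protocol; starting
familiarization from the original pose instead is a switch. Success rates
are percentages so the across-position variance lands on the scale on
which robust and fragile controllers separate by a few hundred. Maze-size
sweeps scale x- and y-dimensions independently ((1, 1) reproduces the
baseline bit for bit); reward-distance sweeps lengthen the rewarded arm
and keep the zone distal. Group comparisons use a Welch t-test on
per-robot variance values (focal group vs pooled rest) with a permutation
alternative.

## Determinism and problem sizes

The simulator is noise-free: identical inputs reproduce trajectories,
logs and weights bit for bit, and the only stochastic stage (the GA) is
driven by a seeded generator. Tests exercise the full protocol at reduced
sizes chosen to keep the suite quick while leaving every code path
identical to full scale: a 60 × 30 cm maze with a 600-step budget for
protocol-heavy checks, sessions of 3–6 trials where only mechanics are
asserted, GA smokes at population 6–16 for a few generations, 300–1000
random series for detector/oracle equivalence, and a few hundred random
poses for sensor invariants. Full-scale quantities (the 100-trial fitness
protocol, the 4000-step budget, the 280-cell grid, the 5000-point
logistic oracle) are asserted at full scale.

## Limitations

* 2-D kinematics only: no wheel slip, no 3-D physics, no sensor noise,
  no hardware interface.
* Several protocol constants are free parameters of the model family
  (maze dimensions, start pose, θ, the Rosenstein m/J/fit_len,
  familiarization clamp outputs, IR gain, gene ranges beyond δ); the
  defaults above are the package's documented choices and all are
  config-exposed.
* The two update rules are one concrete choice within the architecture
  (see Controller); anyone testing alternative forms should swap the two
  isolated functions.
* Comparative findings across robot groups (VTE peaking just after the
  first reward switch, group-level variance separations between VTE
  profiles) require evolving populations of controllers at full GA scale
  (population 100 × 1000 generations per run) and classifying them; the
  package provides the machinery but no such campaign is run in the
  test suite.
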