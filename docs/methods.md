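# Methods

This note documents the models, the numerical choices, and the declared
parameters behind `neuroloop`, and states what the packaged tests do and do
not establish.

## Neuron and synapse model

Neurons are current-based leaky integrate-and-fire points. Defaults
(tau_m 20 ms, V_rest −70 mV, V_reset −70 mV, V_thresh −55 mV, tau_refrac
2 ms, tau_syn 5 ms, R_m 10 MΩ) are conventional cortical-model values; none
of the packaged behaviors depends on their precise magnitudes, only on the
ratios set by the experiment wirings. Integration is exponential Euler per
state variable at a 1 ms default neural step: the membrane update uses the
exact exponential relaxation toward V_rest + R_m·I with I held constant
over the step, so subthreshold trajectories are exact and the only
discretization effects are (a) threshold crossings quantized to the step
and (b) synaptic events delivered on step boundaries (delays round up to
the next step). The dense-timestep test compares first-spike times at 1 ms
against a 10 µs reference on a feedforward chain and bounds the discrepancy
by one coarse step; this holds in the sharp-crossing regime (suprathreshold
drive) and is not claimed for grazing threshold approaches, where crossing
times are intrinsically ill-conditioned.

Devices: the Poisson generator draws a per-step count from
Poisson(rate·dt/1000) per target neuron (independent streams, seeded
deterministically from the master seed by CRC-32 of the device name); the
leaky integrator is a non-spiking membrane that jumps by its weight (mV)
per source spike and relaxes to rest with its own tau (10 ms default) — a
deliberately simple analog readout whose deflection is linear in source
activity; the population-rate recorder divides trailing-window spike counts
by window length and population size.

## World model

The four-wheeled base is reduced to a differential-drive unicycle because
only left/right wheel-speed semantics are exercised; arcs are integrated in
closed form so two half-steps compose exactly to a full step (this is
load-bearing for the pause/resume and step-composability tests). The arm is
a 3-DOF planar revolute chain with joint limits; "moving" the arm during
babbling sets joint angles directly, since the learning task needs
configurations, not trajectories. The camera casts one ray per pixel column
across the horizontal field of view (default 90°) and fills each column
vertically according to the hit screen's apparent angular height; screens
are billboard segments carrying either a solid color or a solid background
with a movable circular target. Rendering is deterministic, so identical
world states give bit-identical images.

## Synchronization and lifecycle

One engine step: apply the outputs buffered by the previous step's transfer
functions; advance the world by cle_dt and the network by cle_dt/neural_dt
inner steps; evaluate all TFs on the frozen snapshots; fire timed events
due at the new boundary. TF outputs are never visible within their own
step — to the simulators or to other TFs — which makes registration order
irrelevant for non-conflicting TFs and the whole loop deterministic under a
fixed master seed. Conflicting writers resolve to the later registration
with a logged warning. Timed events are quantized to engine-step boundaries
(the asynchronous alternative would break determinism) and once-events fire
exactly once across pause/resume cycles.

The lifecycle is a closed transition table; `fail` reaches `halted` from
every state, and re-initialization is the only exit from `stopped` and
`halted`. A second `stop` is rejected explicitly rather than absorbed; the
state outcome is unchanged either way. Reset is parametrized over
{robot_pose, brain, environment}; simulated time and monitor logs
deliberately survive reset so that an experiment remains auditable — a
design choice, as is deriving per-component random streams from the master
seed by stable name hashing.

## Retina model

Each opponent pathway applies, in order: temporal low-pass (tau 50 ms) on
the center channel, a narrow center Gaussian (sigma 1 px), short-term
plasticity, and subtraction of a wider surround Gaussian (sigma 4 px) of
the opposing channel inside a leaky single-compartment accumulator (tau
20 ms), followed by a rectifying nonlinearity. The exact stage order is a
reconstruction: placing STP on the center signal is what produces the
history dependence the model is meant to show — a channel kept silent (for
the green-ON pathway, by a red stimulus) recovers its resource, so a
subsequent green stimulus in that location evokes a larger response than
after a gray history. Swapping the R and G input channels swaps the two
pathway outputs exactly, and disabling STP and the nonlinearity reduces the
chain to a linear spatio-temporal filter (verified by superposition).

The spiking readout stacks the two pathways' stripe currents into 640
layer-1 neurons (current-to-spike conversion) and wires each layer-2
neuron to a stride-1 window of 7 layer-1 neighbors within its pathway,
truncated at the edges; the 640+640 split and the truncation rule are
declared reconstructions around the fixed totals (1,280 neurons, fan-in 7,
320-pixel stripe). The centroid is the spike-count-weighted mean pixel over
a 100 ms trailing window, declared absent below 3 spikes; the eye is a
single pan joint driven by a saturated proportional controller (gain
3 s⁻¹, limit 1.5 rad/s) toward the centroid's bearing.

The packaged tracking scenario overrides two retina defaults in its config
block: depression rate 0.002 /ms (so a dwelling target keeps responding
through STP) and an anisotropic surround of (1, 4) px (rows, columns). The
anisotropy exists because the decoded stripe is one pixel row of a 320×16
image: an isotropic 4 px surround drags the red background from adjacent
rows into the target's receptive fields and cancels the green response.
Injection gains differ per pathway (12 nA green-ON, 2.5 nA red-ON per unit
output) so the sustained red background stays subthreshold in layer 1 while
target-driven activity — and the transient red edges the target leaves
behind — spike; this is what concentrates layer-2 activity at the target.

## Packaged experiments

**Braitenberg.** Eight neurons: three sensors (left-red, right-red, "go"),
three one-to-one relays, two actors. The image's red fractions map to
Poisson rates (r_max 2000 Hz); the go channel at r_max·(1 − max(l, r))
drives search. Cross-wiring (left-red and go → right actor, right-red →
left actor) makes red-on-the-left turn the robot counterclockwise, which is
also the search direction. Wheel speeds come from the two integrator
deflections u via left = k(u_L − β·u_R), right = k(u_R − β·u_L) with k
0.5 m/s, β 0.5, deflection scale 5 mV: equal deflections drive straight,
a dominant right channel yields ω = (v_r − v_l)/W > 0, i.e.
counterclockwise. All weights are controller design tuned for the printed
behavioral contract (one actor dominant without red; rates converging as
red rises); the arena (red screen 135° counterclockwise at ~2.3 m, blue
distractor ahead) and the 12.5 s default duration are part of the declared
scenario. The go relay is kept weak (2 nA/spike) so red-channel input
dominates during approach; the resulting search turn rate is a moderate
~0.5 rad/s, which the search demonstration accommodates with a 16 s run.

**Sensorimotor.** One robot2robot TF alternates babble and evaluation
poses each engine step (commands land one step later, so one iteration
spans two steps). The learner is incremental linear least squares on the
tensor product of (1, cos q_j, sin q_j) over the three joints — 27 basis
functions in which planar revolute-chain forward kinematics is exactly
representable. The normal-equation statistics give a minimum-norm solution,
so the untrained model is the zero map and duplicate consistent samples
leave the fit unchanged. With noiseless observations the error collapses to
machine precision once informative samples exceed the basis size, which is
a strictly stronger property than centimeter accuracy at iteration 40. The
estimator choice (over a Bézier-map regressor) trades surface form for an
exactness guarantee under identical experiment semantics; it is the one
deliberate substitution in the package and is documented here prominently.

**Tracking.** The screen sits 1.5 m ahead, 2.4 m wide; the target circle
(radius 0.15 of screen width, ~48 columns and ~5 rows at the 320×16
resolution) must span several pixel rows or no surround scale can separate
it from the background — smaller targets are a resolution question, not a
model claim. Modes: fixed_eye (sinusoid, period 4 s, amplitude 0.22 of
screen width), step (static target at u = 0.72), pursuit (linear drift
0.06 width/s). Reported measures: Pearson correlation between decoded and
true pixel trajectories after a 2 s settling window (fixed_eye), and mean
absolute bearing error over the final second (step, pursuit).

## What the tests show, and what they do not

All sensory input is produced by the built-in world: noise enters only
through Poisson devices, screens are perfectly saturated colors, kinematics
are exact, and the arm's TCP observations are noiseless. Passing tests
therefore establish the engine's contracts (synchronization, determinism,
lifecycle, reset), the internal consistency of the models, and the
closed-loop behaviors under these idealized conditions — not robustness to
real sensor noise, lighting, dynamics, or model mismatch. The sensorimotor
exactness result in particular depends on noiseless observations of an
exactly representable kinematics; with observation noise the same estimator
degrades gracefully to ordinary least-squares behavior but no longer
reaches machine precision. Problem sizes in the tests and the acceptance
script (12.5–16 s closed-loop runs, 10 learning seeds, 6–10 s tracking
trials) are the package's chosen demonstration scales.
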