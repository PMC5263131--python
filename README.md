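# neuroloop

A desk-scale closed-loop neurorobotics simulator: a spiking neural network
and a 2D robot/world simulation advance in lockstep under a fixed-timestep
engine, coupled by user-defined *transfer functions* that turn sensor data
into neural stimuli and neural activity into motor commands. The package is
for researchers who want to prototype embodied spiking-network controllers —
where the network's input is produced by the very behavior it generates —
without standing up a full robotics middleware stack.

## What is inside

**Spiking simulator** (`neuroloop.spiking`). Leaky integrate-and-fire
populations with exponential-decay current synapses,

    tau_m dV/dt = -(V - V_rest) + R_m I(t),      I(t) = I_syn(t) + I_ext(t)
    tau_s dI_syn/dt = -I_syn  (+ w per presynaptic spike)

integrated by exponential Euler (exact under piecewise-constant current),
with threshold/reset/refractory semantics and delayed weighted projections.
Five device kinds couple the network to the outside: Poisson spike
generators and DC current generators (input), spike recorders,
population-rate recorders and non-spiking leaky integrators (output).

**World simulator** (`neuroloop.world`). A differential-drive robot
(closed-form unicycle kinematics: v = (v_l+v_r)/2, omega = (v_r-v_l)/W), a
3-DOF planar arm with exact forward kinematics, colored billboard screens,
a raycast RGB camera, and a publish/subscribe topic bus.

**Transfer functions** (`neuroloop.tf`). Declarative specs
(robot2neuron, neuron2robot, robot2robot, robot2monitor, neuron2monitor)
binding plain Python functions to topics and devices, validated before the
simulation starts. A library covers the common cases: red-pixel detection,
ratio-to-rate encoding, integrator-potential-to-wheel-command decoding.

**Closed Loop Engine** (`neuroloop.cle`). Both simulators run the same
fixed timestep (default 20 ms outer, 1 ms neural); transfer functions then
execute on the frozen post-step snapshots and their outputs are applied at
the start of the *next* step. That one-step-delay contract makes the two
"parallel" simulations deterministically schedulable and is asserted by
impulse-probe tests in both directions. The engine also owns the simulation
lifecycle (created / initialized / started / paused / stopped / halted), a
parametrized reset (robot pose, brain, environment — independently
selectable), timed events, runtime editing of the brain and TF set, and CSV
monitoring.

**Retina** (`neuroloop.retina`). A microcircuit retina for color-opponent
vision: space-variant Gaussian filtering, temporal low-pass, a
single-compartment accumulator, a static nonlinearity and short-term
plasticity, composed into two red-green opponent pathways, plus a
1,280-neuron two-layer spiking readout (stride-1 windows of 7) and centroid
decoding of a 320-pixel stripe.

**Packaged experiments** (`neuroloop.experiments`): a spiking Braitenberg
vehicle that searches for and approaches a red screen; motor-babbling
forward-model learning on the planar arm (incremental least squares on a
trigonometric tensor basis — exact for planar revolute chains); and
retina-driven visual tracking of a green target.

## Worked example

```sh
python examples/braitenberg_vehicle.py
```

```
time_s  dist_m  red_left  red_right  rate_L_Hz  rate_R_Hz
   0.0    2.26      0.00       0.00        0.0        0.0
   2.5    2.28      0.00       0.00        0.0       20.0
   5.0    2.05      0.24       0.26       60.0       70.0
   7.5    1.60      0.36       0.39       75.0      105.0
   9.9    1.02      0.69       0.69      130.0      125.0
  12.4    0.40      1.00       1.00      155.0      155.0

final distance to red screen: 0.378 m
total rotation while searching + homing: 2.39 rad
```

While no red is visible (first rows) only the right actor neuron fires, so
the wheels counter-rotate and the robot searches counterclockwise. Once red
pixels appear, the two actor rates converge, the wheel commands become
co-directional, and the distance to the screen falls monotonically to well
under half a meter. The other examples (`forward_model_learning.py`,
`retina_tracking.py`, `closed_loop_basics.py`) demonstrate the arm learner,
the retina tracker, and the engine contracts the same way.

A thin CLI wraps the same machinery:

```sh
neuroloop run braitenberg --duration 12500 --seed 1 --out logs/
neuroloop validate my_experiment.yaml
```

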