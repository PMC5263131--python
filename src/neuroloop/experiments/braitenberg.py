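"""Braitenberg vehicle: approach the red screen, search counterclockwise.

An 8-neuron brain (3 sensor, 3 relay, 2 actor neurons) closes the loop
between a camera and two wheels. A robot-to-neuron TF measures the red
pixel fraction in the left and right image halves and converts the two
fractions plus a "go" (no-red-seen) channel into Poisson input rates; the
network relays them to two actor neurons; two leaky-integrator devices
summarize the actor activity; a neuron-to-robot TF turns the two
integrator potentials into wheel speeds.

Wiring (declared): each sensor drives its relay one-to-one; the left-red
relay and the go relay excite the RIGHT actor, and the right-red relay
excites the LEFT actor. A dominant right actor turns the robot
counterclockwise, so with no red anywhere the go channel makes the robot
search counterclockwise, red appearing on the left keeps it turning that
way, and balanced red drives both wheels forward toward the screen. When
the red fraction rises, the two actor rates converge and the wheel
commands become co-directional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cle import Simulation
from ..config import ExperimentConfig, CLEConfig
from ..tf import detect_red, rates_from_ratios, wheel_cmd_from_voltages

__all__ = ["braitenberg_brain", "braitenberg_config", "run_braitenberg",
           "BraitenbergResult", "RED_SCREEN_CENTER"]

# Sensor channel order: left-red, right-red, go.
SENSORS = (0, 1, 2)
RELAYS = (3, 4, 5)
ACTOR_LEFT, ACTOR_RIGHT = 6, 7

# Declared connection strengths (nA per spike) and device constants.
W_IN = 1.0        # Poisson input -> sensor neurons
W_SR = 8.0        # sensor -> relay
W_RA = 8.0        # relay -> actor (red channels)
W_RA_GO = 2.0     # go relay -> right actor (search drive, kept moderate)
LI_WEIGHT = 6.0   # mV deflection per actor spike on the integrators
LI_TAU = 10.0     # ms
R_MAX = 2000.0    # Hz, full-scale Poisson rate
SCALE_MV = 5.0    # integrator deflection mapping to u in [0, 1]
K_SPEED = 0.5     # m/s full-scale wheel speed
BETA = 0.5        # contralateral coupling in the wheel mapping

RED = (255, 0, 0)
BLUE = (0, 0, 255)
# The red screen sits 135 deg counterclockwise from the start heading, so
# the robot must search before it can approach.
RED_SCREEN_CENTER = (-1.6, 1.6)


def braitenberg_brain() -> dict:
    """Declarative description of the 8-neuron Braitenberg brain."""
    projections = []
    for s, r in zip(SENSORS, RELAYS):
        projections.append({"pre": {"population": "brain", "indices": [s]},
                            "post": {"population": "brain", "indices": [r]},
                            "weight": W_SR, "delay_ms": 1.0})
    # left-red relay and go relay -> right actor; right-red relay -> left actor
    projections.append({"pre": {"population": "brain", "indices": [RELAYS[0]]},
                        "post": {"population": "brain", "indices": [ACTOR_RIGHT]},
                        "weight": W_RA, "delay_ms": 1.0})
    projections.append({"pre": {"population": "brain", "indices": [RELAYS[1]]},
                        "post": {"population": "brain", "indices": [ACTOR_LEFT]},
                        "weight": W_RA, "delay_ms": 1.0})
    projections.append({"pre": {"population": "brain", "indices": [RELAYS[2]]},
                        "post": {"population": "brain", "indices": [ACTOR_RIGHT]},
                        "weight": W_RA_GO, "delay_ms": 1.0})
    return {
        "populations": [{"name": "brain", "size": 8}],
        "index_sets": {
            "sensors": {"population": "brain", "indices": list(SENSORS)},
            "relays": {"population": "brain", "indices": list(RELAYS)},
            "actors": {"population": "brain", "indices": [ACTOR_LEFT, ACTOR_RIGHT]},
        },
        "projections": projections,
        "devices": {
            "pg_left": {"kind": "poisson_generator",
                        "target": {"population": "brain", "indices": [SENSORS[0]]},
                        "params": {"weight": W_IN}},
            "pg_right": {"kind": "poisson_generator",
                         "target": {"population": "brain", "indices": [SENSORS[1]]},
                         "params": {"weight": W_IN}},
            "pg_go": {"kind": "poisson_generator",
                      "target": {"population": "brain", "indices": [SENSORS[2]]},
                      "params": {"weight": W_IN}},
            "li_left": {"kind": "leaky_integrator",
                        "target": {"population": "brain", "indices": [ACTOR_LEFT]},
                        "params": {"tau_ms": LI_TAU, "weight": LI_WEIGHT}},
            "li_right": {"kind": "leaky_integrator",
                         "target": {"population": "brain", "indices": [ACTOR_RIGHT]},
                         "params": {"tau_ms": LI_TAU, "weight": LI_WEIGHT}},
            "rate_left": {"kind": "population_rate",
                          "target": {"population": "brain", "indices": [ACTOR_LEFT]},
                          "params": {"window_ms": 200.0}},
            "rate_right": {"kind": "population_rate",
                           "target": {"population": "brain",
                                      "indices": [ACTOR_RIGHT]},
                           "params": {"window_ms": 200.0}},
            "brain_spikes": {"kind": "spike_recorder", "target": "brain"},
        },
    }


# -- transfer function bodies ----------------------------------------------

def eye_tf(ctx) -> None:
    """robot2neuron: red fractions -> Poisson rates on the three sensors."""
    image = ctx.topics["sensor/camera"]
    left, right = detect_red(image)
    r_l, r_r, r_go = rates_from_ratios(left, right, ctx.params.get("r_max", R_MAX))
    ctx.devices["pg_left"].set_rate(r_l)
    ctx.devices["pg_right"].set_rate(r_r)
    ctx.devices["pg_go"].set_rate(r_go)
    ctx.monitor("red_ratios", (left, right))


def wheel_tf(ctx) -> None:
    """neuron2robot: integrator potentials -> differential wheel command."""
    v_l = ctx.devices["li_left"].voltage
    v_r = ctx.devices["li_right"].voltage
    cmd = wheel_cmd_from_voltages(
        v_l, v_r, v_rest=ctx.params.get("v_rest", -70.0),
        scale_mv=ctx.params.get("scale_mv", SCALE_MV),
        k=ctx.params.get("k", K_SPEED), beta=ctx.params.get("beta", BETA))
    ctx.publish("cmd/wheels", cmd)
    ctx.monitor("wheel_cmd", cmd)
    ctx.monitor("li_voltages", (v_l, v_r))


def rate_monitor_tf(ctx) -> None:
    """neuron2monitor: the two actor firing rates."""
    ctx.monitor("actor_rates",
                (ctx.devices["rate_left"].rate(), ctx.devices["rate_right"].rate()))


def spike_monitor_tf(ctx) -> None:
    """neuron2monitor: stream newly recorded spikes with their own times."""
    records = ctx.devices["recorder"].records
    start = ctx.state.get("n_seen", 0)
    for rec in records[start:]:
        ctx.monitor("brain_spikes", rec.neuron_id, t_ms=rec.time_ms)
    ctx.state["n_seen"] = len(records)


def pose_monitor_tf(ctx) -> None:
    """robot2monitor: the robot pose trajectory."""
    ctx.monitor("pose", ctx.topics["sensor/pose"])


def braitenberg_config(variant: str = "red", seed: int = 0,
                       duration_ms: float | None = None) -> ExperimentConfig:
    """Packaged Braitenberg experiment configuration.

    Variants: ``red`` — a red screen is present (135 deg counterclockwise
    of the start heading) and a blue distractor sits ahead; ``no_red`` —
    both screens blue, so the robot searches indefinitely; ``event`` — the
    search-side screen starts blue and a timed event turns it red mid-run.
    """
    if variant not in ("red", "no_red", "event"):
        raise ValueError(f"unknown variant {variant!r}")
    cx, cy = RED_SCREEN_CENTER
    facing = np.arctan2(cy, cx) + np.pi / 2  # tangent; screen faces origin
    screens = [
        {"id": "screen_search", "center": (cx, cy), "width": 1.2,
         "height": 2.5, "orientation": float(facing),
         "color": RED if variant == "red" else BLUE},
        {"id": "screen_ahead", "center": (2.5, 0.0), "width": 1.0,
         "height": 2.0, "orientation": np.pi / 2, "color": BLUE},
    ]
    events = []
    if variant == "event":
        events.append({"at_ms": 4000.0, "action": "set_screen_color",
                       "args": {"screen": "screen_search", "color": RED}})
    return ExperimentConfig(
        name=f"braitenberg-{variant}",
        cle=CLEConfig(cle_dt_ms=20.0, neural_dt_ms=1.0, seed=seed,
                      max_duration_ms=duration_ms),
        world={
            "robot": {"x": 0.0, "y": 0.0, "theta": 0.0, "track_width": 0.4,
                      "camera": {"width": 64, "height": 64, "fov_deg": 90}},
            "screens": screens,
        },
        brain=braitenberg_brain(),
        tfs=[
            {"name": "eye", "kind": "robot2neuron",
             "subscriptions": ["sensor/camera"],
             "devices": {"pg_left": "pg_left", "pg_right": "pg_right",
                         "pg_go": "pg_go"},
             "body": eye_tf, "params": {"r_max": R_MAX}},
            {"name": "wheels", "kind": "neuron2robot",
             "publications": ["cmd/wheels"],
             "devices": {"li_left": "li_left", "li_right": "li_right"},
             "body": wheel_tf,
             "params": {"scale_mv": SCALE_MV, "k": K_SPEED, "beta": BETA}},
            {"name": "rates", "kind": "neuron2monitor",
             "devices": {"rate_left": "rate_left", "rate_right": "rate_right"},
             "body": rate_monitor_tf},
            {"name": "spikes", "kind": "neuron2monitor",
             "devices": {"recorder": "brain_spikes"},
             "body": spike_monitor_tf},
            {"name": "pose", "kind": "robot2monitor",
             "subscriptions": ["sensor/pose"],
             "body": pose_monitor_tf},
        ],
        events=events,
        monitors=["red_ratios", "wheel_cmd", "li_voltages", "actor_rates",
                  "brain_spikes", "pose"],
    )


@dataclass
class BraitenbergResult:
    """Run outcome: the simulation handle plus convenience trajectories."""

    sim: Simulation
    times_ms: np.ndarray
    poses: np.ndarray        # (n, 3): x, y, theta per step
    red_ratios: np.ndarray   # (n, 2)
    actor_rates: np.ndarray  # (n, 2): (left, right) Hz
    wheel_cmds: np.ndarray   # (n, 2)

    @property
    def monitor(self):
        return self.sim.monitor

    def distance_to(self, point) -> np.ndarray:
        p = np.asarray(point)
        return np.hypot(self.poses[:, 0] - p[0], self.poses[:, 1] - p[1])

    def cumulative_rotation(self) -> float:
        """Total signed heading change over the run (rad, unwrapped)."""
        dtheta = np.diff(np.unwrap(self.poses[:, 2]))
        return float(dtheta.sum())


def run_braitenberg(variant: str = "red", duration_ms: float = 12500.0,
                    seed: int = 1, config: ExperimentConfig | None = None
                    ) -> BraitenbergResult:
    """Run the packaged Braitenberg experiment end to end."""
    cfg = config if config is not None else braitenberg_config(variant, seed=seed)
    sim = Simulation(cfg)
    sim.initialize()
    sim.run(duration_ms)
    mon = sim.monitor
    return BraitenbergResult(
        sim=sim,
        times_ms=mon.times("pose"),
        poses=mon.values("pose"),
        red_ratios=mon.values("red_ratios"),
        actor_rates=mon.values("actor_rates"),
        wheel_cmds=mon.values("wheel_cmd"),
    )
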