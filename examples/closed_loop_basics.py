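"""Anatomy of a closed-loop experiment, from scratch.

Builds a minimal experiment by hand — a 2-neuron brain, a world with one
screen, one transfer function in each direction, and a timed event — then
demonstrates the engine's contracts: the one-step delay between the two
simulators, the lifecycle state machine, and the parametrized reset.
"""

from neuroloop.cle import Simulation
from neuroloop.config import CLEConfig, ExperimentConfig


def stimulate(ctx):
    """robot2neuron: constant Poisson drive into the population."""
    ctx.devices["pg"].set_rate(600.0)


def report(ctx):
    """neuron2robot: integrator potential -> forward speed."""
    u = max(0.0, (ctx.devices["li"].voltage + 70.0) / 5.0)
    ctx.publish("cmd/wheels", (0.05 * u, 0.05 * u))
    ctx.monitor("potential_mv", ctx.devices["li"].voltage)


config = ExperimentConfig(
    name="basics",
    cle=CLEConfig(cle_dt_ms=20.0, neural_dt_ms=1.0, seed=4),
    world={"robot": {"camera": {"width": 16, "height": 16, "fov_deg": 90}},
           "screens": [{"id": "s", "center": (2.0, 0.0), "width": 1.0,
                        "color": (0, 0, 255)}]},
    brain={"populations": [{"name": "p", "size": 2}],
           "devices": {"pg": {"kind": "poisson_generator", "target": "p",
                              "params": {"weight": 1.5}},
                       "li": {"kind": "leaky_integrator", "target": "p"}}},
    tfs=[{"name": "in", "kind": "robot2neuron",
          "subscriptions": ["sensor/camera"], "devices": {"pg": "pg"},
          "body": stimulate},
         {"name": "out", "kind": "neuron2robot",
          "publications": ["cmd/wheels"], "devices": {"li": "li"},
          "body": report}],
    events=[{"at_ms": 500.0, "action": "set_screen_color",
             "args": {"screen": "s", "color": (255, 0, 0)}}],
    monitors=["potential_mv"],
)

sim = Simulation(config)
print("state after construction:", sim.state)
sim.initialize()
print("state after initialize:  ", sim.state)
sim.start()

sim.run_step()
print(f"\nafter 1 step: t={sim.time_ms:.0f} ms, robot x={sim.world.robot.pose.x}")
print("  (the stimulus TF ran, but its output is buffered: one-step delay)")
sim.run_step()
print(f"after 2 steps: x={sim.world.robot.pose.x:.4f} m; screen still "
      f"{sim.world.screens['s'].color}")

sim.run(600.0)
print(f"\nafter {sim.time_ms:.0f} ms the timed event has fired: screen is "
      f"{sim.world.screens['s'].color}")
print(f"integrator potential: {sim.monitor.values('potential_mv')[-1]:.1f} mV")

sim.reset({"robot_pose"})
print(f"\nreset(robot_pose): x={sim.world.robot.pose.x} m, but time is "
      f"still {sim.time_ms:.0f} ms and the screen stays red")
sim.pause()
print("state after pause:", sim.state)
sim.stop()
print("state after stop: ", sim.state)
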