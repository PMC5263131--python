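"""Closed Loop Engine tests: lifecycle, synchronization, reset, editing."""

import numpy as np
import pytest

from neuroloop.cle import (
    LIFECYCLE_STATES,
    ResetSelector,
    Simulation,
    SimulationLifecycle,
    TransitionError,
    lifecycle_transitions,
)
from neuroloop.config import CLEConfig, ExperimentConfig
from neuroloop.tf import TFEvaluationError


def minimal_config(seed=0, tfs=(), monitors=(), brain=None, events=(),
                   cle_dt=20.0):
    return ExperimentConfig(
        name="minimal",
        cle=CLEConfig(cle_dt_ms=cle_dt, neural_dt_ms=1.0, seed=seed),
        world={"robot": {"camera": {"width": 8, "height": 8, "fov_deg": 90}},
               "screens": [{"id": "s", "center": (2.0, 0.0), "width": 1.0,
                            "color": (0, 0, 255)}]},
        brain=brain if brain is not None else {
            "populations": [{"name": "p", "size": 2}],
            "devices": {
                "dc": {"kind": "dc_generator", "target": "p"},
                "li": {"kind": "leaky_integrator", "target": "p"},
            },
        },
        tfs=list(tfs), monitors=list(monitors), events=list(events),
    )


class TestLifecycleTable:
    def test_transition_table_is_exactly_the_declared_one(self):
        expected = {
            ("created", "initialize"): "initialized",
            ("initialized", "start"): "started",
            ("started", "pause"): "paused",
            ("paused", "start"): "started",
            ("started", "stop"): "stopped",
            ("paused", "stop"): "stopped",
            ("stopped", "initialize"): "initialized",
            ("halted", "initialize"): "initialized",
        }
        for state in LIFECYCLE_STATES:
            expected[(state, "fail")] = "halted"
        assert lifecycle_transitions() == expected

    def test_fail_reaches_halted_from_every_state(self):
        for state in LIFECYCLE_STATES:
            lc = SimulationLifecycle()
            lc.state = state
            assert lc.transition("fail") == "halted"

    def test_started_pause_start_roundtrip(self):
        lc = SimulationLifecycle()
        lc.transition("initialize")
        lc.transition("start")
        assert lc.transition("pause") == "paused"
        assert lc.transition("start") == "started"

    def test_start_from_created_rejected(self):
        lc = SimulationLifecycle()
        with pytest.raises(TransitionError):
            lc.transition("start")
        assert lc.state == "created"

    def test_second_stop_rejected_state_unchanged(self):
        lc = SimulationLifecycle()
        lc.transition("initialize")
        lc.transition("start")
        lc.transition("stop")
        with pytest.raises(TransitionError):
            lc.transition("stop")
        assert lc.state == "stopped"

    def test_transition_log_records_history(self):
        lc = SimulationLifecycle()
        lc.transition("initialize")
        lc.transition("start")
        assert lc.log == [("created", "initialize", "initialized"),
                          ("initialized", "start", "started")]


class TestInitialization:
    def test_valid_config_initializes_at_time_zero(self):
        sim = Simulation(minimal_config())
        sim.initialize()
        assert sim.state == "initialized"
        assert sim.time_ms == 0.0

    def test_double_initialize_rejected(self):
        sim = Simulation(minimal_config())
        sim.initialize()
        with pytest.raises(TransitionError):
            sim.initialize()

    def test_unknown_population_reference_halts_with_diagnostic(self):
        cfg = minimal_config(tfs=[{
            "name": "bad", "kind": "robot2neuron",
            "subscriptions": ["sensor/camera"], "devices": {"d": "ghost"},
            "body": lambda ctx: None}])
        sim = Simulation(cfg)
        with pytest.raises(Exception):
            sim.initialize()
        assert sim.state == "halted"
        assert "ghost" in sim.diagnostic

    def test_run_step_requires_started(self):
        sim = Simulation(minimal_config())
        sim.initialize()
        with pytest.raises(TransitionError):
            sim.run_step()


class TestOneStepDelay:
    def test_robot_to_brain_impulse_arrives_one_step_late(self):
        """A device setting written by a TF during step n affects the
        neural state during step n+1, never step n."""
        def impulse(ctx):
            if ctx.t_ms == ctx.params["fire_at"]:
                ctx.devices["dc"].set_amplitude(1.0)

        cfg = minimal_config(tfs=[{
            "name": "imp", "kind": "robot2neuron",
            "subscriptions": ["sensor/pose"], "devices": {"dc": "dc"},
            "body": impulse, "params": {"fire_at": 20.0}}])
        sim = Simulation(cfg)
        sim.initialize()
        sim.start()
        v_rest = sim.net.populations["p"].params.v_rest
        sim.run_step()  # step 1: TF fires at its end (t=20)
        assert np.all(sim.net.populations["p"].v == v_rest)
        sim.run_step()  # step 2: buffered amplitude applied
        assert np.all(sim.net.populations["p"].v > v_rest)

    def test_brain_to_robot_command_moves_world_one_step_late(self):
        def drive(ctx):
            ctx.publish("cmd/wheels", (0.5, 0.5))

        cfg = minimal_config(tfs=[{
            "name": "drive", "kind": "neuron2robot",
            "publications": ["cmd/wheels"], "devices": {"li": "li"},
            "body": drive}])
        sim = Simulation(cfg)
        sim.initialize()
        sim.start()
        sim.run_step()  # TF publishes at the end of step 1
        assert sim.world.robot.pose.x == 0.0
        sim.run_step()  # command applied at the start of step 2
        assert sim.world.robot.pose.x == pytest.approx(0.5 * 0.020)


class TestClockAgreement:
    def test_both_simulators_report_k_times_dt(self):
        sim = Simulation(minimal_config())
        sim.initialize()
        sim.start()
        for k in range(1, 26):
            sim.run_step()
            assert sim.time_ms == k * 20.0
            assert sim.world.time_ms == k * 20.0
            assert sim.net.time_ms == k * 20.0


def stochastic_config(seed=3):
    """A small closed loop with Poisson noise for trajectory comparisons."""
    def feedback(ctx):
        ctx.devices["pg"].set_rate(800.0)
        ctx.monitor("v", ctx.devices["li"].voltage)
        ctx.publish("cmd/wheels", (0.1, 0.2))

    return ExperimentConfig(
        name="stochastic",
        cle=CLEConfig(cle_dt_ms=20.0, neural_dt_ms=1.0, seed=seed),
        world={"robot": {"camera": {"width": 8, "height": 8, "fov_deg": 90}}},
        brain={
            "populations": [{"name": "p", "size": 4}],
            "projections": [{"pre": "p", "post": "p", "weight": 0.8}],
            "devices": {
                "pg": {"kind": "poisson_generator", "target": "p",
                       "params": {"weight": 1.5}},
                "li": {"kind": "leaky_integrator", "target": "p"},
                "rec": {"kind": "spike_recorder", "target": "p"},
            },
        },
        tfs=[{"name": "fb", "kind": "robot2neuron",
              "subscriptions": ["sensor/pose"],
              "publications": ["cmd/wheels"],
              "devices": {"pg": "pg", "li": "li"}, "body": feedback}],
        monitors=["v"],
    )


def state_fingerprint(sim):
    pose = sim.world.robot.pose
    return (round(pose.x, 12), round(pose.y, 12), round(pose.theta, 12),
            tuple(sim.net.populations["p"].v.round(12)),
            tuple((r.neuron_id, r.time_ms)
                  for r in sim.net.devices["rec"].records))


class TestPauseResumeAndDeterminism:
    def test_pause_resume_is_trajectory_neutral(self):
        a = Simulation(stochastic_config())
        a.initialize()
        a.start()
        for _ in range(30):
            a.run_step()

        b = Simulation(stochastic_config())
        b.initialize()
        b.start()
        for _ in range(15):
            b.run_step()
        b.pause()
        b.start()
        for _ in range(15):
            b.run_step()
        assert state_fingerprint(a) == state_fingerprint(b)

    def test_identical_seeds_identical_trajectories(self):
        def run():
            sim = Simulation(stochastic_config(seed=11))
            sim.initialize()
            sim.run(600.0)
            return state_fingerprint(sim), tuple(sim.monitor.values("v"))

        assert run() == run()

    def test_different_seeds_diverge(self):
        def run(seed):
            sim = Simulation(stochastic_config(seed=seed))
            sim.initialize()
            sim.run(600.0)
            return state_fingerprint(sim)

        assert run(1) != run(2)


class TestReset:
    def make_running(self):
        sim = Simulation(stochastic_config())
        sim.initialize()
        sim.start()
        for _ in range(20):
            sim.run_step()
        return sim

    def test_empty_selector_rejected(self):
        sim = self.make_running()
        with pytest.raises(ValueError):
            sim.reset(set())
        with pytest.raises(ValueError):
            ResetSelector(frozenset())

    def test_unknown_selector_rejected(self):
        with pytest.raises(ValueError):
            ResetSelector(frozenset({"flux_capacitor"}))

    def test_robot_pose_reset_leaves_brain_untouched(self):
        sim = self.make_running()
        v_before = sim.net.populations["p"].v.copy()
        assert sim.world.robot.pose.x != 0.0
        sim.reset({"robot_pose"})
        assert sim.world.robot.pose.x == 0.0
        np.testing.assert_array_equal(sim.net.populations["p"].v, v_before)

    def test_brain_reset_reinitializes_membranes_not_pose(self):
        sim = self.make_running()
        x_before = sim.world.robot.pose.x
        sim.reset({"brain"})
        p = sim.net.populations["p"]
        assert np.all(p.v == p.params.v_rest)
        assert sim.net.devices["rec"].records == []
        assert sim.world.robot.pose.x == x_before

    def test_full_reset_matches_fresh_initialization_except_time_and_logs(self):
        sim = self.make_running()
        t_before = sim.time_ms
        n_records = len(sim.monitor.records["v"])
        sim.reset({"robot_pose", "brain", "environment"})

        fresh = Simulation(stochastic_config())
        fresh.initialize()
        assert sim.world.robot.pose.x == fresh.world.robot.pose.x
        np.testing.assert_array_equal(sim.net.populations["p"].v,
                                      fresh.net.populations["p"].v)
        assert sim.time_ms == t_before  # time preserved
        assert len(sim.monitor.records["v"]) == n_records  # logs preserved

    def test_reset_requires_live_simulation(self):
        sim = Simulation(stochastic_config())
        sim.initialize()
        with pytest.raises(TransitionError):
            sim.reset({"brain"})


class TestRuntimeEditing:
    def test_replacing_tf_changes_behavior_from_next_step_only(self):
        sim = Simulation(stochastic_config())
        sim.initialize()
        sim.start()
        for _ in range(5):
            sim.run_step()

        def stop_cmd(ctx):
            ctx.publish("cmd/wheels", (0.0, 0.0))

        sim.set_tf({"name": "fb", "kind": "robot2robot",
                    "subscriptions": ["sensor/pose"],
                    "publications": ["cmd/wheels"], "body": stop_cmd})
        x0 = sim.world.robot.pose.x
        sim.run_step()  # old buffered command still applies here
        x1 = sim.world.robot.pose.x
        sim.run_step()  # new TF's stop command lands
        x2 = sim.world.robot.pose.x
        sim.run_step()
        assert x1 > x0  # swap did not retroactively cancel the old command
        assert x2 == x1  # stop command landed exactly one step later
        assert sim.world.robot.pose.x == x2  # still stopped

    def test_invalid_brain_swap_rejected_simulation_continues(self):
        sim = Simulation(stochastic_config())
        sim.initialize()
        sim.start()
        sim.run_step()
        old_net = sim.net
        with pytest.raises(Exception):
            sim.set_brain({"populations": [{"name": "other", "size": 1}]})
        assert sim.net is old_net
        sim.run_step()
        assert sim.state == "started"

    def test_removing_only_motor_tf_makes_robot_coast(self):
        sim = Simulation(stochastic_config())
        sim.initialize()
        sim.start()
        for _ in range(3):
            sim.run_step()
        sim.remove_tf("fb")
        vl_before = sim.world.robot.vl
        sim.run_step()
        sim.run_step()
        assert sim.world.robot.vl == vl_before  # coasts on last command
        assert sim.world.robot.pose.x > 0.0


class TestFaultHandling:
    def test_tf_exception_halts_simulation(self):
        def explode(ctx):
            raise ValueError("bad tf")

        cfg = minimal_config(tfs=[{"name": "x", "kind": "robot2robot",
                                   "body": explode}])
        sim = Simulation(cfg)
        sim.initialize()
        sim.start()
        with pytest.raises(TFEvaluationError):
            sim.run_step()
        assert sim.state == "halted"
        assert "bad tf" in sim.diagnostic

    def test_cle_dt_must_be_multiple_of_neural_dt(self):
        with pytest.raises(ValueError):
            CLEConfig(cle_dt_ms=2.5, neural_dt_ms=1.0)
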