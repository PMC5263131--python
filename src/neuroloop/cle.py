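"""Closed Loop Engine: fixed-timestep orchestration of brain and body.

The engine advances the world simulator and the spiking simulator by the
same fixed timestep, then evaluates the transfer functions on the frozen
post-step snapshots and buffers their outputs for application at the start
of the next step. The two simulations are logically parallel: neither may
observe the other's in-step outputs, so sequential execution is a valid
(and deterministic) scheduling. The resulting synchronization contract is
the one-step delay: information produced in step n is first consumable by
the other side in step n+1.

A simulation instance also owns the lifecycle state machine
(created / initialized / started / paused / stopped / halted), the
parametrized reset (robot pose, brain, environment — selectable
independently), and runtime editing of the brain and the TF set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import CLEConfig, ExperimentConfig, build_world, load_config
from .events import WorkflowMachine
from .spiking import ConfigurationError, SimulationFault, build_network, stable_seed
from .world import WorldError
from .tf import (
    MonitorLog,
    TFEvaluationError,
    TFOutputs,
    TFRegistry,
    TFValidationError,
    TransferFunctionSpec,
    resolve_body,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LIFECYCLE_STATES",
    "LIFECYCLE_ACTIONS",
    "lifecycle_transitions",
    "SimulationLifecycle",
    "TransitionError",
    "ResetSelector",
    "Simulation",
]

LIFECYCLE_STATES = ("created", "initialized", "started", "paused",
                    "stopped", "halted")
LIFECYCLE_ACTIONS = ("initialize", "start", "pause", "stop", "fail")

RESET_TARGETS = frozenset({"robot_pose", "brain", "environment"})


def lifecycle_transitions() -> dict[tuple[str, str], str]:
    """The legal lifecycle transition table.

    created --initialize--> initialized --start--> started;
    started <--start/pause--> paused; started/paused --stop--> stopped;
    stopped/halted --initialize--> initialized (re-initialization is the
    only way out of the terminal states); and fail --> halted from every
    state.
    """
    table = {
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
        table[(state, "fail")] = "halted"
    return table


class TransitionError(RuntimeError):
    """An illegal lifecycle transition was requested; state is unchanged."""


class SimulationLifecycle:
    """Explicit lifecycle state machine with a transition log."""

    def __init__(self) -> None:
        self.state = "created"
        self.log: list[tuple[str, str, str]] = []  # (from, action, to)
        self._table = lifecycle_transitions()

    def can(self, action: str) -> bool:
        return (self.state, action) in self._table

    def transition(self, action: str) -> str:
        if action not in LIFECYCLE_ACTIONS:
            raise TransitionError(f"unknown lifecycle action {action!r}")
        key = (self.state, action)
        if key not in self._table:
            raise TransitionError(
                f"illegal transition: action {action!r} from state {self.state!r}")
        new = self._table[key]
        self.log.append((self.state, action, new))
        self.state = new
        return new


@dataclass(frozen=True)
class ResetSelector:
    """Which parts of a running simulation a reset restores."""

    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        flags = frozenset(self.flags)
        if not flags:
            raise ValueError("reset selector must name at least one target")
        unknown = flags - RESET_TARGETS
        if unknown:
            raise ValueError(f"unknown reset targets {sorted(unknown)}; "
                             f"expected subset of {sorted(RESET_TARGETS)}")
        object.__setattr__(self, "flags", flags)


# Topics the world exposes; TFs may subscribe to sensors and publish commands.
SENSOR_TOPICS = ("sensor/pose", "sensor/pan", "sensor/camera",
                 "sensor/arm_angles", "sensor/tcp")
COMMAND_TOPICS = ("cmd/wheels", "cmd/pan_vel", "cmd/arm_angles",
                  "cmd/arm_velocities", "cmd/screen_target")


class Simulation:
    """One closed-loop simulation instance driven by an experiment config."""

    def __init__(self, config) -> None:
        self.config: ExperimentConfig = load_config(config)
        self.lifecycle = SimulationLifecycle()
        self.time_ms = 0.0
        self.diagnostic: str | None = None
        self.world = None
        self.net = None
        self.registry: TFRegistry | None = None
        self.events: WorkflowMachine | None = None
        self.monitor: MonitorLog | None = None
        self._pending = TFOutputs()

    # -- lifecycle --------------------------------------------------------

    @property
    def state(self) -> str:
        return self.lifecycle.state

    def transition(self, action: str) -> str:
        return self.lifecycle.transition(action)

    def fail(self, diagnostic: str) -> None:
        self.diagnostic = diagnostic
        self.lifecycle.transition("fail")
        logger.error("simulation halted: %s", diagnostic)

    def initialize(self) -> "Simulation":
        """Validate the whole configuration and build both simulators.

        Any validation failure leaves the simulation halted with a
        diagnostic, mirroring the fail-on-error lifecycle rule.
        """
        if not self.lifecycle.can("initialize"):
            raise TransitionError(
                f"cannot initialize from state {self.state!r}")
        try:
            self._build()
        except (ConfigurationError, TFValidationError, ValueError, KeyError) as exc:
            self.fail(f"initialization failed: {exc}")
            raise
        self.lifecycle.transition("initialize")
        self.time_ms = 0.0
        return self

    def _build(self) -> None:
        cfg = self.config
        seed = cfg.cle.seed
        self.world = build_world(cfg.world)
        self.net = build_network(cfg.brain, dt_ms=cfg.cle.neural_dt_ms)
        self.net.seed(stable_seed(seed, "brain"))
        self.monitor = MonitorLog(tuple(cfg.monitors))
        self.registry = TFRegistry(self.monitor)
        topics = self.known_topics()
        for tf_cfg in cfg.tfs:
            spec = self._make_tf_spec(tf_cfg)
            self.registry.register(spec, self.net, topics,
                                   seed=stable_seed(seed, f"tf:{spec.name}"))
        self.events = WorkflowMachine(cfg.timed_events())
        self._pending = TFOutputs()
        self.world.publish_sensors()

    def _make_tf_spec(self, tf_cfg) -> TransferFunctionSpec:
        if isinstance(tf_cfg, TransferFunctionSpec):
            return tf_cfg
        d = dict(tf_cfg)
        d["body"] = resolve_body(d["body"])
        return TransferFunctionSpec(
            name=d["name"], kind=d["kind"], body=d["body"],
            subscriptions=d.get("subscriptions", ()),
            publications=d.get("publications", ()),
            devices=d.get("devices", {}), params=d.get("params", {}))

    def known_topics(self) -> set[str]:
        return set(SENSOR_TOPICS) | set(COMMAND_TOPICS) | set(self.config.extra_topics)

    def start(self) -> "Simulation":
        self.lifecycle.transition("start")
        return self

    def pause(self) -> "Simulation":
        self.lifecycle.transition("pause")
        return self

    def stop(self) -> "Simulation":
        self.lifecycle.transition("stop")
        return self

    # -- stepping ---------------------------------------------------------

    def run_step(self) -> "Simulation":
        """Advance the closed loop by one engine timestep.

        Order: (1) apply the outputs the TFs buffered at the end of the
        previous step — device settings to the brain, topic publications to
        the world; (2) step the world and the brain by cle_dt (the brain in
        cle_dt/neural_dt inner steps) — logically in parallel on the same
        inputs; (3) evaluate the TFs on the completed snapshots and buffer
        their outputs; (4) fire due timed events at the new step boundary.
        """
        if self.state != "started":
            raise TransitionError(f"run_step requires state 'started', "
                                  f"not {self.state!r}")
        cfg = self.config.cle
        try:
            self._apply_pending()
            self.world.step(cfg.cle_dt_ms)
            for _ in range(cfg.inner_steps):
                self.net.step()
            snapshot = {t: self.world.bus.read(t) for t in self.world.bus.topics()}
            t_next = self.time_ms + cfg.cle_dt_ms
            self._pending = self.registry.evaluate(self.net, snapshot, t_next)
            self.time_ms = t_next
            self.events.tick(self.world, self.time_ms)
        except (SimulationFault, TFEvaluationError, WorldError) as exc:
            self.fail(str(exc))
            raise
        return self

    def _apply_pending(self) -> None:
        for devname, settings in self._pending.device_settings.items():
            dev = self.net.devices.get(devname)
            if dev is None:
                continue  # brain was swapped; stale setting dropped
            for attr, value in settings.items():
                if attr != "_writers":
                    setattr(dev, attr, value)
        for topic, message in self._pending.publication_order:
            self.world.bus.publish(topic, message)
            if topic.startswith("cmd/"):
                self.world.apply_command(topic, message)
        self._pending = TFOutputs()

    def run(self, duration_ms: float) -> "Simulation":
        """Run for a duration (auto-starting if only initialized)."""
        if self.state == "initialized":
            self.start()
        n = int(round(duration_ms / self.config.cle.cle_dt_ms))
        limit = self.config.cle.max_duration_ms
        for _ in range(n):
            if limit is not None and self.time_ms >= limit:
                break
            self.run_step()
        return self

    # -- reset and runtime editing ---------------------------------------

    def reset(self, selector) -> "Simulation":
        """Restore the selected parts to their initial values.

        Unselected parts, the simulated time, and the monitor logs are all
        untouched, so a reset mid-experiment stays auditable.
        """
        if self.state not in ("started", "paused"):
            raise TransitionError(
                f"reset requires state started/paused, not {self.state!r}")
        if not isinstance(selector, ResetSelector):
            selector = ResetSelector(frozenset(selector))
        if "robot_pose" in selector.flags:
            self.world.reset_robot_pose()
        if "brain" in selector.flags:
            self.net.reset_state()
            self._pending.device_settings.clear()
        if "environment" in selector.flags:
            self.world.reset_environment()
        return self

    def set_brain(self, description: dict) -> "Simulation":
        """Swap the brain description at a step boundary, atomically.

        The new network is built and every registered TF is re-validated
        against it before the swap; on any failure the old brain remains
        active and the simulation continues.
        """
        if self.state not in ("started", "paused", "initialized"):
            raise TransitionError(
                f"set_brain requires a live simulation, not {self.state!r}")
        new_net = build_network(description, dt_ms=self.config.cle.neural_dt_ms)
        new_net.seed(stable_seed(self.config.cle.seed, "brain"))
        topics = self.known_topics()
        for spec in self.registry.specs:
            self.registry.validate(spec, new_net, topics)
        self.net = new_net
        self.config.brain = description
        self._pending.device_settings.clear()
        return self

    def set_tf(self, tf_cfg) -> "Simulation":
        if self.state not in ("started", "paused", "initialized"):
            raise TransitionError(
                f"set_tf requires a live simulation, not {self.state!r}")
        spec = self._make_tf_spec(tf_cfg)
        self.registry.register(spec, self.net, self.known_topics(),
                               seed=stable_seed(self.config.cle.seed,
                                                f"tf:{spec.name}"))
        return self

    def remove_tf(self, name: str) -> "Simulation":
        self.registry.remove(name)
        return self
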