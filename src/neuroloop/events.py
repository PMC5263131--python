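"""Timed experiment-workflow events.

A small state machine that mutates the world at declared simulated times
(e.g., switching a screen's color mid-run). Events are quantized to
closed-loop step boundaries: an event scheduled at time ``at`` fires at
the first step boundary where simulated time reaches ``at``, in time
order with declaration order breaking ties. Once-events fire exactly once
across pause/resume cycles; events never fire while the simulation is
paused because the engine only ticks the machine from within a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .world import World, WorldError
from .spiking import SimulationFault

__all__ = ["TimedEvent", "WorkflowMachine", "ACTIONS"]


def _act_set_screen_color(world: World, args: dict) -> None:
    world.set_screen_color(args["screen"], args["color"])


def _act_set_screen_target(world: World, args: dict) -> None:
    world.set_screen_target(args["screen"], args.get("u"))


def _act_set_background(world: World, args: dict) -> None:
    world.background = tuple(int(c) for c in args["color"])


ACTIONS = {
    "set_screen_color": _act_set_screen_color,
    "set_screen_target": _act_set_screen_target,
    "set_background": _act_set_background,
}


@dataclass(frozen=True)
class TimedEvent:
    """One scheduled world mutation: fire ``action(args)`` at time ``at_ms``."""

    at_ms: float
    action: str
    args: dict = field(default_factory=dict)
    once: bool = True

    def __post_init__(self) -> None:
        if self.at_ms < 0:
            raise ValueError("event time must be >= 0")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown event action {self.action!r}; "
                             f"expected one of {sorted(ACTIONS)}")


class WorkflowMachine:
    """Fires timed events against the world, exactly once per once-event."""

    def __init__(self, events: list[TimedEvent] = ()) -> None:
        self.events = list(events)
        # stable sort by time; declaration order breaks ties
        self._order = sorted(range(len(self.events)),
                             key=lambda i: (self.events[i].at_ms, i))
        self.fired: set[int] = set()

    def tick(self, world: World, t_ms: float) -> None:
        """Fire all unfired events with ``at_ms <= t_ms``, in order."""
        for i in self._order:
            ev = self.events[i]
            if ev.at_ms > t_ms:
                break
            if ev.once and i in self.fired:
                continue
            try:
                ACTIONS[ev.action](world, ev.args)
            except WorldError as exc:
                raise SimulationFault(f"event at t={ev.at_ms} ms failed: {exc}") from exc
            self.fired.add(i)

    def reset_fired(self) -> None:
        self.fired.clear()
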