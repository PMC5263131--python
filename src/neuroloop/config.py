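"""Experiment configuration: one declarative description per experiment.

An :class:`ExperimentConfig` binds a world layout, a brain description, a
transfer-function set, timed events, monitor channels and engine timing —
the complete recipe the closed-loop engine needs to instantiate a run.
Configs are plain dicts underneath and round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .events import TimedEvent
from .world import Camera, DifferentialDriveRobot, PlanarArm, Pose2D, Screen, World

__all__ = ["CLEConfig", "ExperimentConfig", "build_world", "load_config"]


@dataclass(frozen=True)
class CLEConfig:
    """Closed-loop timing: the engine step, the inner neural step, the seed.

    ``cle_dt_ms`` must be an integer multiple of ``neural_dt_ms``; the
    default 20 ms outer / 1 ms inner pairing matches a camera-rate control
    loop over a conventionally stepped point-neuron simulation.
    """

    cle_dt_ms: float = 20.0
    neural_dt_ms: float = 1.0
    seed: int = 0
    max_duration_ms: float | None = None

    def __post_init__(self) -> None:
        if self.cle_dt_ms <= 0 or self.neural_dt_ms <= 0:
            raise ValueError("timesteps must be > 0")
        ratio = self.cle_dt_ms / self.neural_dt_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"cle_dt ({self.cle_dt_ms} ms) must be an integer multiple of "
                f"neural_dt ({self.neural_dt_ms} ms)")

    @property
    def inner_steps(self) -> int:
        return int(round(self.cle_dt_ms / self.neural_dt_ms))


@dataclass
class ExperimentConfig:
    """Full declarative description of one closed-loop experiment."""

    name: str
    cle: CLEConfig = field(default_factory=CLEConfig)
    world: dict = field(default_factory=dict)
    brain: dict = field(default_factory=dict)
    tfs: list = field(default_factory=list)       # list of TF spec dicts
    events: list = field(default_factory=list)    # list of TimedEvent or dicts
    monitors: list = field(default_factory=list)  # declared monitor channels
    extra_topics: list = field(default_factory=list)

    def timed_events(self) -> list[TimedEvent]:
        out = []
        for ev in self.events:
            if isinstance(ev, TimedEvent):
                out.append(ev)
            else:
                out.append(TimedEvent(at_ms=ev["at_ms"], action=ev["action"],
                                      args=ev.get("args", {}),
                                      once=ev.get("once", True)))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cle = d.get("cle", {})
        return cls(
            name=d.get("name", "experiment"),
            cle=cle if isinstance(cle, CLEConfig) else CLEConfig(**cle),
            world=d.get("world", {}),
            brain=d.get("brain", {}),
            tfs=list(d.get("tfs", [])),
            events=list(d.get("events", [])),
            monitors=list(d.get("monitors", [])),
            extra_topics=list(d.get("extra_topics", [])),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["events"] = [asdict(e) if isinstance(e, TimedEvent) else e
                       for e in self.events]
        # TF bodies may be callables; hash/serialize them by qualified name
        tfs = []
        for tf in self.tfs:
            tf = dict(tf)
            body = tf.get("body")
            if callable(body):
                tf["body"] = f"{body.__module__}:{body.__qualname__}"
            tfs.append(tf)
        d["tfs"] = tfs
        return d

    def config_hash(self) -> str:
        """Stable content hash of the configuration (for run manifests)."""
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return repr(o)
        blob = json.dumps(self.to_dict(), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_world(world_cfg: dict) -> World:
    """Instantiate a :class:`~neuroloop.world.World` from its config block."""
    rc = dict(world_cfg.get("robot", {}))
    cam_cfg = dict(rc.pop("camera", {}))
    if "fov_deg" in cam_cfg:
        cam_cfg["fov_rad"] = np.deg2rad(cam_cfg.pop("fov_deg"))
    camera = Camera(**cam_cfg)
    pose = Pose2D(rc.pop("x", 0.0), rc.pop("y", 0.0), rc.pop("theta", 0.0))
    robot = DifferentialDriveRobot(pose=pose, camera=camera,
                                   track_width=rc.pop("track_width", 0.4))
    arm = None
    if "arm" in world_cfg and world_cfg["arm"] is not None:
        ac = dict(world_cfg["arm"])
        arm = PlanarArm(
            lengths=tuple(ac.get("lengths", (0.3, 0.25, 0.15))),
            angles=ac.get("angles"),
            limits=tuple(tuple(l) for l in ac["limits"]) if "limits" in ac else None,
        )
    screens = []
    for sc in world_cfg.get("screens", []):
        sc = dict(sc)
        sc["center"] = tuple(sc["center"])
        sc["color"] = tuple(sc.get("color", (0, 0, 255)))
        if "target_color" in sc:
            sc["target_color"] = tuple(sc["target_color"])
        screens.append(Screen(**sc))
    background = tuple(world_cfg.get("background", (128, 128, 128)))
    return World(robot=robot, arm=arm, screens=screens, background=background)


def load_config(source) -> ExperimentConfig:
    """Load a config from an ExperimentConfig, dict, YAML path, or builtin name.

    Builtin names (``braitenberg``, ``sensorimotor``, ``retina-tracking``)
    resolve to the packaged experiment configurations.
    """
    if isinstance(source, ExperimentConfig):
        return source
    if isinstance(source, dict):
        return ExperimentConfig.from_dict(source)
    text = str(source)
    if Path(text).exists():
        return ExperimentConfig.from_yaml(text)
    from . import experiments
    builtin = experiments.BUILTIN_CONFIGS.get(text.replace("_", "-"))
    if builtin is None:
        raise FileNotFoundError(
            f"no config file {text!r} and no builtin experiment of that name "
            f"(builtins: {sorted(experiments.BUILTIN_CONFIGS)})")
    return builtin()
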