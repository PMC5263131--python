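"""Transfer-function (TF) framework: the brain/body coupling layer.

A transfer function is a user-supplied function that translates robot
sensor data into neural stimuli (``robot2neuron``), neural activity into
motor commands (``neuron2robot``), robot data into robot commands without
touching the brain (``robot2robot``), or either side into monitoring
records (``robot2monitor``, ``neuron2monitor``).

TFs are registered declaratively (name, kind, topic subscriptions/
publications, device bindings, body) and evaluated once per closed-loop
step on frozen snapshots of both simulations. All outputs — device
settings, topic publications, monitor records — are buffered and applied
by the engine at the start of the *next* step, which realizes the
one-step-delay synchronization contract and gives TF bodies snapshot
isolation from each other.
"""

from __future__ import annotations

import importlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .spiking import (
    DCGeneratorDevice,
    LeakyIntegratorDevice,
    Network,
    PoissonGeneratorDevice,
    PopulationRateDevice,
    SpikeRecorderDevice,
    INPUT_DEVICE_KINDS,
    OUTPUT_DEVICE_KINDS,
)
from .world import CameraImage

logger = logging.getLogger(__name__)

__all__ = [
    "TF_KINDS",
    "TransferFunctionSpec",
    "TFValidationError",
    "TFEvaluationError",
    "TFRegistry",
    "TFOutputs",
    "MonitorLog",
    "MonitorRecord",
    "detect_red",
    "rates_from_ratios",
    "wheel_cmd_from_voltages",
    "resolve_body",
]

TF_KINDS = ("robot2neuron", "neuron2robot", "robot2robot",
            "robot2monitor", "neuron2monitor")
MONITOR_KINDS = ("robot2monitor", "neuron2monitor")


class TFValidationError(ValueError):
    """TF specification rejected before simulation start."""


class TFEvaluationError(RuntimeError):
    """A TF body raised during evaluation; treated as a simulation fault."""


@dataclass
class TransferFunctionSpec:
    """Declarative description of one transfer function.

    body is a callable ``body(ctx)`` receiving a :class:`TFContext`; it
    reads ``ctx.topics`` and output-device proxies, and emits through
    ``ctx.publish``, ``ctx.monitor`` and input-device proxy setters.
    Statefulness goes through ``ctx.state`` (a per-TF dict that survives
    across steps); everything else must be pure.
    """

    name: str
    kind: str
    body: Callable
    subscriptions: tuple = ()
    publications: tuple = ()
    devices: dict = field(default_factory=dict)  # local name -> network device name
    params: dict = field(default_factory=dict)   # constants exposed as ctx.params

    def __post_init__(self) -> None:
        if self.kind not in TF_KINDS:
            raise TFValidationError(
                f"TF {self.name!r}: unknown kind {self.kind!r}")
        self.subscriptions = tuple(self.subscriptions)
        self.publications = tuple(self.publications)


@dataclass(frozen=True)
class MonitorRecord:
    time_ms: float
    source: str     # TF name
    channel: str
    value: object   # scalar or 1-D vector


class MonitorLog:
    """Append-only store of monitor records, one stream per declared channel."""

    def __init__(self, channels: tuple[str, ...] = ()) -> None:
        self.channels: list[str] = list(channels)
        self.records: dict[str, list[MonitorRecord]] = {c: [] for c in self.channels}

    def declare(self, channel: str) -> None:
        if channel not in self.records:
            self.channels.append(channel)
            self.records[channel] = []

    def append(self, rec: MonitorRecord) -> None:
        if rec.channel not in self.records:
            raise TFValidationError(f"undeclared monitor channel {rec.channel!r}")
        self.records[rec.channel].append(rec)

    def values(self, channel: str) -> np.ndarray:
        return np.array([r.value for r in self.records[channel]])

    def times(self, channel: str) -> np.ndarray:
        return np.array([r.time_ms for r in self.records[channel]])

    def to_csv(self, channel: str) -> str:
        """CSV text for one channel, columns ``time_ms,channel,value...``.

        Vector values expand into ``value_0..value_k`` columns; spike
        channels (records whose value is an (id, ...) tuple tagged by the
        channel name ending in ``spikes``) use ``time_ms,neuron_id``.
        """
        recs = self.records[channel]
        if channel.endswith("spikes"):
            lines = ["time_ms,neuron_id"]
            for r in recs:
                ids = np.atleast_1d(r.value)
                lines.extend(f"{r.time_ms:g},{int(i)}" for i in ids)
            return "\n".join(lines) + "\n"
        width = 1
        for r in recs:
            v = np.atleast_1d(np.asarray(r.value, dtype=float))
            width = max(width, v.size)
        header = ("time_ms,channel,value" if width == 1 else
                  "time_ms,channel," + ",".join(f"value_{i}" for i in range(width)))
        lines = [header]
        for r in recs:
            v = np.atleast_1d(np.asarray(r.value, dtype=float))
            lines.append(f"{r.time_ms:g},{channel}," + ",".join(f"{x:.10g}" for x in v))
        return "\n".join(lines) + "\n"


@dataclass
class TFOutputs:
    """Buffered outputs of one evaluation round, applied at the next step."""

    device_settings: dict = field(default_factory=dict)  # device name -> {attr: value}
    publications: dict = field(default_factory=dict)     # topic -> message (last wins)
    publication_order: list = field(default_factory=list)
    monitor_records: list = field(default_factory=list)


class _InputDeviceProxy:
    """Write-only proxy for an input-side device; setters go to the buffer."""

    def __init__(self, name, device, buffer, owner):
        self._name, self._device, self._buffer, self._owner = name, device, buffer, owner

    def set_rate(self, rate) -> None:
        self._write("rate", rate)

    def set_amplitude(self, amplitude) -> None:
        self._write("amplitude", amplitude)

    def _write(self, attr, value) -> None:
        if not hasattr(self._device, attr):
            raise TFEvaluationError(
                f"device {self._name!r} ({self._device.kind}) has no setting {attr!r}")
        slot = self._buffer.device_settings.setdefault(self._name, {})
        if attr in slot.get("_writers", {}) and slot["_writers"][attr] != self._owner:
            logger.warning("device %r setting %r written by both %r and %r; "
                           "later registration wins", self._name, attr,
                           slot["_writers"][attr], self._owner)
        slot[attr] = value
        slot.setdefault("_writers", {})[attr] = self._owner


class _OutputDeviceProxy:
    """Read-only proxy over an output-side device at snapshot time."""

    def __init__(self, name, device, t_now):
        self._name, self._device, self._t = name, device, t_now

    @property
    def voltage(self) -> float:
        return self._device.voltage

    def rate(self, window_ms: float | None = None) -> float:
        return self._device.rate(self._t, window_ms)

    def spike_counts(self, window_ms: float, id_offset: int = 0,
                     n: int | None = None) -> np.ndarray:
        return self._device.counts_in_window(self._t, window_ms, id_offset, n)

    @property
    def records(self):
        return self._device.records


class TFContext:
    """Everything a TF body may see and emit during one evaluation."""

    def __init__(self, spec, topics, devices, buffer, state, rng, t_ms):
        self.t_ms = t_ms
        self.topics = topics        # frozen dict of subscribed topic values
        self.devices = devices      # local name -> proxy
        self.state = state          # per-TF mutable dict, survives steps
        self.rng = rng              # per-TF seeded generator
        self.params = spec.params   # declared constants for this TF
        self._spec = spec
        self._buffer = buffer

    def publish(self, topic: str, message) -> None:
        if self._spec.kind in MONITOR_KINDS:
            raise TFEvaluationError(
                f"monitor TF {self._spec.name!r} may not publish to topics")
        if topic not in self._spec.publications:
            raise TFEvaluationError(
                f"TF {self._spec.name!r} publishes to undeclared topic {topic!r}")
        if topic in self._buffer.publications:
            logger.warning("topic %r written twice in one step; last writer wins", topic)
        self._buffer.publications[topic] = message
        self._buffer.publication_order.append((topic, message))

    def monitor(self, channel: str, value, t_ms: float | None = None) -> None:
        t = self.t_ms if t_ms is None else float(t_ms)
        self._buffer.monitor_records.append(
            MonitorRecord(t, self._spec.name, channel, value))


class TFRegistry:
    """Ordered registry of transfer functions; order = evaluation order.

    Re-registering an existing name replaces the TF in place (runtime
    editing), keeping its position in the evaluation order.
    """

    def __init__(self, monitor: MonitorLog | None = None) -> None:
        self._specs: dict[str, TransferFunctionSpec] = {}
        self.monitor = monitor if monitor is not None else MonitorLog()
        self._state: dict[str, dict] = {}
        self._rng: dict[str, np.random.Generator] = {}

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    @property
    def specs(self) -> list[TransferFunctionSpec]:
        return list(self._specs.values())

    def validate(self, spec: TransferFunctionSpec, net: Network,
                 known_topics: set[str]) -> None:
        """Reject malformed specs before simulation start.

        Checks the kind discipline (which sides a TF of each kind may
        touch), topic existence, and device binding resolvability.
        """
        in_devs, out_devs = [], []
        for local, devname in spec.devices.items():
            if devname not in net.devices:
                raise TFValidationError(
                    f"TF {spec.name!r}: unknown device {devname!r}")
            kind = net.devices[devname].kind
            (in_devs if kind in INPUT_DEVICE_KINDS else out_devs).append(local)
        for topic in spec.subscriptions:
            if topic not in known_topics:
                raise TFValidationError(
                    f"TF {spec.name!r}: unknown topic {topic!r}")
        for topic in spec.publications:
            if topic not in known_topics:
                raise TFValidationError(
                    f"TF {spec.name!r}: unknown publication topic {topic!r}")
        k = spec.kind
        if k == "robot2neuron":
            if not spec.subscriptions or not in_devs:
                raise TFValidationError(
                    f"robot2neuron TF {spec.name!r} needs >=1 subscription "
                    "and >=1 input-side device")
        elif k == "neuron2robot":
            if not out_devs or not spec.publications:
                raise TFValidationError(
                    f"neuron2robot TF {spec.name!r} needs >=1 output-side device "
                    "and >=1 publication")
        elif k == "robot2robot":
            if spec.devices:
                raise TFValidationError(
                    f"robot2robot TF {spec.name!r} must not touch devices")
        elif k in MONITOR_KINDS:
            if spec.publications:
                raise TFValidationError(
                    f"monitor TF {spec.name!r} may not publish to topics")
            if k == "robot2monitor" and spec.devices:
                raise TFValidationError(
                    f"robot2monitor TF {spec.name!r} must not bind devices")
            if k == "neuron2monitor" and in_devs:
                raise TFValidationError(
                    f"neuron2monitor TF {spec.name!r} may not bind input devices")

    def register(self, spec: TransferFunctionSpec, net: Network,
                 known_topics: set[str], seed: int = 0) -> None:
        self.validate(spec, net, known_topics)
        replacing = spec.name in self._specs
        self._specs[spec.name] = spec
        if not replacing:
            self._state[spec.name] = {}
            self._rng[spec.name] = np.random.default_rng(seed)

    def remove(self, name: str) -> None:
        if name not in self._specs:
            raise TFValidationError(f"no TF named {name!r}")
        del self._specs[name]
        self._state.pop(name, None)
        self._rng.pop(name, None)

    def evaluate(self, net: Network, topic_snapshot: dict, t_ms: float) -> TFOutputs:
        """Run every TF body, in registration order, on frozen snapshots.

        Outputs are buffered into a :class:`TFOutputs`; monitor records are
        appended to the log immediately (they leave the loop). A body
        exception is wrapped into :class:`TFEvaluationError` for the engine
        to translate into a lifecycle fault.
        """
        buffer = TFOutputs()
        for spec in self._specs.values():
            topics = {k: topic_snapshot.get(k) for k in spec.subscriptions}
            proxies = {}
            for local, devname in spec.devices.items():
                dev = net.devices[devname]
                if dev.kind in INPUT_DEVICE_KINDS:
                    proxies[local] = _InputDeviceProxy(devname, dev, buffer, spec.name)
                else:
                    proxies[local] = _OutputDeviceProxy(devname, dev, t_ms)
            ctx = TFContext(spec, topics, proxies, buffer,
                            self._state[spec.name], self._rng[spec.name], t_ms)
            try:
                spec.body(ctx)
            except TFEvaluationError:
                raise
            except Exception as exc:
                raise TFEvaluationError(
                    f"TF {spec.name!r} raised {type(exc).__name__}: {exc}") from exc
        for rec in buffer.monitor_records:
            self.monitor.append(rec)
        return buffer

    def state_of(self, name: str) -> dict:
        return self._state[name]


# ---------------------------------------------------------------------------
# Reusable TF library
# ---------------------------------------------------------------------------

def detect_red(image: CameraImage) -> tuple[float, float]:
    """Fraction of red pixels in the left and right halves of an image.

    A pixel counts as red iff R >= 2G, R >= 2B and R >= 64. For odd widths
    the center column belongs to the left half. Returns (left, right) in
    [0, 1] as fractions of each half's pixel count.
    """
    px = image.pixels.astype(np.int32)
    red = (px[..., 0] >= 2 * px[..., 1]) & (px[..., 0] >= 2 * px[..., 2]) \
        & (px[..., 0] >= 64)
    split = (image.width + 1) // 2
    left, right = red[:, :split], red[:, split:]
    rr = 0.0 if right.size == 0 else float(right.mean())
    return float(left.mean()), rr


def rates_from_ratios(left_ratio: float, right_ratio: float,
                      r_max: float = 2000.0) -> tuple[float, float, float]:
    """Map red-pixel ratios to firing rates for the three sensor channels.

    Returns (rate_left, rate_right, rate_go) in Hz: the two sided channels
    scale with their half's red fraction, the "go" channel is active when
    little red is seen anywhere and drives the search behavior.
    """
    if not (0 <= left_ratio <= 1 and 0 <= right_ratio <= 1):
        raise ValueError("ratios must lie in [0, 1]")
    return (r_max * left_ratio, r_max * right_ratio,
            r_max * (1.0 - max(left_ratio, right_ratio)))


def wheel_cmd_from_voltages(v_left: float, v_right: float, *,
                            v_rest: float = -70.0, scale_mv: float = 10.0,
                            k: float = 1.0, beta: float = 0.5
                            ) -> tuple[float, float]:
    """Translate two leaky-integrator potentials into wheel speeds (m/s).

    Deflections above rest are normalized to u in [0, 1] by ``scale_mv``;
    then ``left = k*(uL - beta*uR)`` and ``right = k*(uR - beta*uL)``.
    Equal deflections drive both wheels forward at the same speed; a
    dominant right channel turns the robot counterclockwise (right wheel
    forward, left backward or slower), and symmetrically for the left.
    """
    if not np.all(np.isfinite([v_left, v_right])):
        raise ValueError("integrator potentials must be finite")
    u_l = float(np.clip((v_left - v_rest) / scale_mv, 0.0, 1.0))
    u_r = float(np.clip((v_right - v_rest) / scale_mv, 0.0, 1.0))
    return k * (u_l - beta * u_r), k * (u_r - beta * u_l)


def resolve_body(ref) -> Callable:
    """Resolve a TF body given as a callable or a ``module:function`` path."""
    if callable(ref):
        return ref
    if isinstance(ref, str) and ":" in ref:
        mod, _, name = ref.partition(":")
        fn = getattr(importlib.import_module(mod), name)
        if not callable(fn):
            raise TFValidationError(f"{ref!r} is not callable")
        return fn
    raise TFValidationError(f"cannot resolve TF body {ref!r}")
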