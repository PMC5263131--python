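"""Point-neuron spiking simulator.

Leaky integrate-and-fire (LIF) populations with exponential-decay current
synapses, delayed projections, and the five device kinds used by the
transfer-function framework: Poisson spike generators and DC current
generators on the input side; spike recorders, population-rate recorders and
leaky integrators on the output side.

Integration is exponential Euler per state variable, which is exact for the
membrane equation under piecewise-constant input current, so subthreshold
trajectories carry no truncation error — only threshold crossings and
synaptic event times are quantized to the neural timestep.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "LIFParams",
    "Population",
    "PopulationView",
    "Projection",
    "DeviceSpec",
    "SpikeRecord",
    "Network",
    "build_network",
    "ConfigurationError",
    "SimulationFault",
    "DEVICE_KINDS",
    "INPUT_DEVICE_KINDS",
    "OUTPUT_DEVICE_KINDS",
]

DEVICE_KINDS = (
    "poisson_generator",
    "dc_generator",
    "spike_recorder",
    "population_rate",
    "leaky_integrator",
)
INPUT_DEVICE_KINDS = ("poisson_generator", "dc_generator")
OUTPUT_DEVICE_KINDS = ("spike_recorder", "population_rate", "leaky_integrator")


class ConfigurationError(ValueError):
    """Invalid network, device or parameter configuration."""


class SimulationFault(RuntimeError):
    """Non-recoverable fault during stepping (e.g., non-finite state)."""


def stable_seed(master_seed: int, name: str) -> int:
    """Derive a per-component seed from a master seed and a component name.

    Uses CRC32 of the name so the derivation is independent of Python's
    per-process hash randomization; result is kept below 2**31.
    """
    return (int(master_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron parameters.

    tau_m      membrane time constant (ms)
    v_rest     resting potential (mV)
    v_reset    post-spike reset potential (mV)
    v_thresh   firing threshold (mV)
    tau_refrac absolute refractory period (ms)
    tau_syn    synaptic current decay time constant (ms)
    r_m        membrane resistance (MOhm); r_m * I[nA] gives mV
    """

    tau_m: float = 20.0
    v_rest: float = -70.0
    v_reset: float = -70.0
    v_thresh: float = -55.0
    tau_refrac: float = 2.0
    tau_syn: float = 5.0
    r_m: float = 10.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_refrac", "tau_syn", "r_m"):
            if getattr(self, name) <= 0 and name != "tau_refrac":
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tau_refrac < 0:
            raise ConfigurationError("tau_refrac must be >= 0")
        if not (self.v_thresh > self.v_reset):
            raise ConfigurationError("v_thresh must exceed v_reset")
        if not (self.v_thresh > self.v_rest):
            raise ConfigurationError("v_thresh must exceed v_rest")


@dataclass(frozen=True)
class SpikeRecord:
    """One emitted spike: global neuron index and spike time in ms."""

    neuron_id: int
    time_ms: float


class Population:
    """A named set of LIF neurons sharing parameters.

    State arrays (length ``size``): membrane potential ``v`` (mV), synaptic
    current ``i_syn`` (nA), external current ``i_ext`` (nA, rebuilt each
    step from input devices), refractory countdown ``refrac`` (ms).
    """

    def __init__(self, name: str, size: int, params: LIFParams | None = None,
                 offset: int = 0) -> None:
        if size < 1:
            raise ConfigurationError(f"population {name!r}: size must be >= 1")
        self.name = name
        self.size = int(size)
        self.params = params or LIFParams()
        self.offset = offset  # global id of neuron 0
        self.reset_state()

    def reset_state(self) -> None:
        p = self.params
        self.v = np.full(self.size, p.v_rest, dtype=float)
        self.i_syn = np.zeros(self.size)
        self.i_ext = np.zeros(self.size)
        self.refrac = np.zeros(self.size)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Population({self.name!r}, size={self.size})"


@dataclass(frozen=True)
class PopulationView:
    """A slice of a population: the addressing unit for projections/devices."""

    population: str
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Projection:
    """Weighted, delayed connection between two population views.

    ``weights`` has shape (len(pre), len(post)) in nA added to the
    postsynaptic synaptic current per presynaptic spike (signed).
    ``delay_ms`` is rounded up to the nearest multiple of the neural dt.
    """

    pre: PopulationView
    post: PopulationView
    weights: np.ndarray
    delay_ms: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.weights.shape != (len(self.pre), len(self.post)):
            raise ConfigurationError(
                f"projection weights shape {self.weights.shape} != "
                f"({len(self.pre)}, {len(self.post)})")
        if self.delay_ms <= 0:
            raise ConfigurationError("projection delay must be > 0")


@dataclass(frozen=True)
class DeviceSpec:
    """Declarative description of a device to attach to a population view.

    kind: one of DEVICE_KINDS; params are kind-specific:
      poisson_generator: rate (Hz), weight (nA/spike)
      dc_generator:      amplitude (nA)
      spike_recorder:    (none)
      population_rate:   window_ms
      leaky_integrator:  tau_ms, weight (mV deflection per source spike)
    """

    kind: str
    target: PopulationView | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DEVICE_KINDS:
            raise ConfigurationError(
                f"unknown device kind {self.kind!r}; expected one of {DEVICE_KINDS}")


class _Device:
    def __init__(self, name: str, target: PopulationView):
        if target is None or len(target) == 0:
            raise ConfigurationError(f"device {name!r}: target must be non-empty")
        self.name = name
        self.target = target

    def reset_state(self) -> None:  # pragma: no cover - overridden where stateful
        pass


class PoissonGeneratorDevice(_Device):
    """Per-step Poisson spike source: each target neuron receives
    count ~ Poisson(rate * dt / 1000) spikes, each adding ``weight`` nA."""

    kind = "poisson_generator"

    def __init__(self, name, target, rate=0.0, weight=1.0):
        super().__init__(name, target)
        self.weight = float(weight)
        self.rate = rate
        self.rng = np.random.default_rng(0)

    @property
    def rate(self) -> np.ndarray:
        return self._rate

    @rate.setter
    def rate(self, value) -> None:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (len(self.target),)).copy()
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"device {self.name!r}: rate must be finite and >= 0")
        self._rate = arr

    def seed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def draw(self, dt_ms: float) -> np.ndarray:
        return self.rng.poisson(self._rate * dt_ms / 1000.0)

    def reset_state(self) -> None:
        self._rate = np.zeros(len(self.target))


class DCGeneratorDevice(_Device):
    """Constant current injection: ``amplitude`` nA added each step."""

    kind = "dc_generator"

    def __init__(self, name, target, amplitude=0.0):
        super().__init__(name, target)
        self.amplitude = amplitude

    @property
    def amplitude(self) -> np.ndarray:
        return self._amplitude

    @amplitude.setter
    def amplitude(self, value) -> None:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (len(self.target),)).copy()
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"device {self.name!r}: amplitude must be finite")
        self._amplitude = arr

    def reset_state(self) -> None:
        self._amplitude = np.zeros(len(self.target))


class SpikeRecorderDevice(_Device):
    """Records (time_ms, global neuron id) for every spike of its targets."""

    kind = "spike_recorder"

    def __init__(self, name, target):
        super().__init__(name, target)
        self.records: list[SpikeRecord] = []

    def record(self, time_ms: float, global_ids: np.ndarray) -> None:
        self.records.extend(SpikeRecord(int(g), float(time_ms)) for g in global_ids)

    def counts_in_window(self, t_now: float, window_ms: float,
                         id_offset: int = 0, n: int | None = None) -> np.ndarray:
        """Spike counts per target neuron in the trailing window (t_now-w, t_now]."""
        n = n if n is not None else len(self.target)
        counts = np.zeros(n, dtype=int)
        for rec in reversed(self.records):
            if rec.time_ms <= t_now - window_ms:
                break
            idx = rec.neuron_id - id_offset
            if 0 <= idx < n:
                counts[idx] += 1
        return counts

    def reset_state(self) -> None:
        self.records = []


class PopulationRateDevice(_Device):
    """Mean firing rate of the target over a trailing window, in Hz."""

    kind = "population_rate"

    def __init__(self, name, target, window_ms=100.0):
        super().__init__(name, target)
        if window_ms <= 0:
            raise ConfigurationError("population_rate window must be > 0")
        self.window_ms = float(window_ms)
        self._events: list[tuple[float, int]] = []  # (time, spike count)

    def record(self, time_ms: float, count: int) -> None:
        if count:
            self._events.append((time_ms, count))

    min_window_ms = 0.0  # set to the neural dt when attached to a network

    def rate(self, t_now: float, window_ms: float | None = None) -> float:
        w = self.window_ms if window_ms is None else window_ms
        if w < self.min_window_ms:
            raise ConfigurationError(
                f"rate window {w} ms shorter than the neural dt "
                f"{self.min_window_ms} ms")
        total = sum(c for t, c in self._events if t_now - w < t <= t_now)
        return 1000.0 * total / (w * len(self.target))

    def reset_state(self) -> None:
        self._events = []


class LeakyIntegratorDevice(_Device):
    """Non-spiking leaky membrane driven by source spikes.

    Each source spike deflects the device potential by ``weight`` mV; the
    potential relaxes back to ``v_rest`` with time constant ``tau_ms``.
    The device never spikes (its threshold is +inf), so its potential is an
    analog summary of recent source activity, usable as a motor signal.
    """

    kind = "leaky_integrator"

    def __init__(self, name, target, tau_ms=10.0, weight=1.0, v_rest=-70.0):
        super().__init__(name, target)
        if tau_ms <= 0:
            raise ConfigurationError("leaky_integrator tau must be > 0")
        self.tau_ms = float(tau_ms)
        self.weight = float(weight)
        self.v_rest = float(v_rest)
        self.v = self.v_rest

    def decay(self, dt_ms: float) -> None:
        self.v = self.v_rest + (self.v - self.v_rest) * np.exp(-dt_ms / self.tau_ms)

    def add_spikes(self, count: int) -> None:
        self.v += self.weight * count

    @property
    def voltage(self) -> float:
        return self.v

    def reset_state(self) -> None:
        self.v = self.v_rest


_DEVICE_CLASSES = {
    "poisson_generator": PoissonGeneratorDevice,
    "dc_generator": DCGeneratorDevice,
    "spike_recorder": SpikeRecorderDevice,
    "population_rate": PopulationRateDevice,
    "leaky_integrator": LeakyIntegratorDevice,
}


class Network:
    """A spiking network: populations, projections, devices and a clock.

    Neurons have global ids assigned by population insertion order; named
    index sets map experiment-level names (e.g. ``sensors``) to population
    views so transfer functions can address neurons symbolically.
    """

    def __init__(self, dt_ms: float = 1.0) -> None:
        if dt_ms <= 0:
            raise ConfigurationError("neural dt must be > 0")
        self.dt_ms = float(dt_ms)
        self.populations: dict[str, Population] = {}
        self.projections: list[Projection] = []
        self.devices: dict[str, _Device] = {}
        self.index_sets: dict[str, PopulationView] = {}
        self.time_ms = 0.0
        self.step_index = 0
        self._queue: dict[int, dict[str, np.ndarray]] = {}
        self.spike_log: list[SpikeRecord] = []

    # -- construction -----------------------------------------------------

    def add_population(self, name: str, size: int,
                       params: LIFParams | None = None) -> Population:
        if name in self.populations:
            raise ConfigurationError(f"duplicate population {name!r}")
        offset = sum(p.size for p in self.populations.values())
        pop = Population(name, size, params, offset=offset)
        self.populations[name] = pop
        return pop

    def view(self, population: str, indices=None) -> PopulationView:
        if population not in self.populations:
            raise ConfigurationError(f"unknown population {population!r}")
        pop = self.populations[population]
        if indices is None:
            indices = range(pop.size)
        idx = tuple(int(i) for i in indices)
        if not idx:
            raise ConfigurationError(f"empty index set into population {population!r}")
        if any(i < 0 or i >= pop.size for i in idx):
            raise ConfigurationError(
                f"indices {idx} out of range for population {population!r} "
                f"of size {pop.size}")
        return PopulationView(population, idx)

    def define_index_set(self, name: str, population: str, indices) -> PopulationView:
        v = self.view(population, indices)
        self.index_sets[name] = v
        return v

    def resolve(self, ref) -> PopulationView:
        """Resolve a population/index-set reference to a view.

        Accepts a PopulationView, an index-set name, a population name, or
        a dict {"population": ..., "indices": [...]}.
        """
        if isinstance(ref, PopulationView):
            if ref.population not in self.populations:
                raise ConfigurationError(f"unknown population {ref.population!r}")
            return ref
        if isinstance(ref, str):
            if ref in self.index_sets:
                return self.index_sets[ref]
            if ref in self.populations:
                return self.view(ref)
            raise ConfigurationError(f"unresolvable population reference {ref!r}")
        if isinstance(ref, dict):
            return self.view(ref["population"], ref.get("indices"))
        raise ConfigurationError(f"cannot resolve population reference {ref!r}")

    def connect(self, pre, post, weights, delay_ms: float = 1.0) -> Projection:
        pre_v, post_v = self.resolve(pre), self.resolve(post)
        w = np.asarray(weights, dtype=float)
        if w.ndim == 0:
            w = np.full((len(pre_v), len(post_v)), float(w))
        proj = Projection(pre_v, post_v, w, delay_ms)
        self.projections.append(proj)
        return proj

    def attach_device(self, name: str, spec: DeviceSpec) -> _Device:
        if name in self.devices:
            raise ConfigurationError(f"duplicate device {name!r}")
        target = self.resolve(spec.target)
        dev = _DEVICE_CLASSES[spec.kind](name, target, **spec.params)
        if isinstance(dev, PopulationRateDevice):
            dev.min_window_ms = self.dt_ms
            if dev.window_ms < self.dt_ms:
                raise ConfigurationError(
                    f"device {name!r}: window {dev.window_ms} ms shorter than "
                    f"the neural dt {self.dt_ms} ms")
        self.devices[name] = dev
        return dev

    def seed(self, master_seed: int) -> None:
        """Seed every stochastic device deterministically from a master seed."""
        for name, dev in self.devices.items():
            if isinstance(dev, PoissonGeneratorDevice):
                dev.seed(stable_seed(master_seed, f"device:{name}"))

    # -- introspection ----------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations.values())

    def global_ids(self, view: PopulationView) -> np.ndarray:
        pop = self.populations[view.population]
        return pop.offset + np.asarray(view.indices, dtype=int)

    # -- dynamics ---------------------------------------------------------

    def reset_state(self) -> None:
        """Reinitialize membrane states, device buffers and event queues.

        Structure (populations, projections, devices) is kept; the clock is
        kept too — resetting time is the caller's decision.
        """
        for pop in self.populations.values():
            pop.reset_state()
        for dev in self.devices.values():
            dev.reset_state()
        self._queue.clear()
        self.spike_log = []

    def step(self, dt_ms: float | None = None) -> list[SpikeRecord]:
        """Advance the network by one neural timestep; return spikes emitted.

        Order within a step: deliver queued synaptic events, apply device
        input currents, exponential-Euler membrane update, threshold/reset,
        queue outgoing synaptic events, update output devices.
        """
        dt = self.dt_ms if dt_ms is None else float(dt_ms)
        if abs(dt - self.dt_ms) > 1e-12:
            raise ConfigurationError(
                f"step dt {dt} != configured neural dt {self.dt_ms}")

        # 1. deliver synaptic events scheduled for this step
        due = self._queue.pop(self.step_index, None)
        if due:
            for pop_name, amounts in due.items():
                self.populations[pop_name].i_syn += amounts

        # 2. input devices
        for pop in self.populations.values():
            pop.i_ext[:] = 0.0
        poisson_counts: dict[str, np.ndarray] = {}
        for name, dev in self.devices.items():
            if isinstance(dev, PoissonGeneratorDevice):
                counts = dev.draw(dt)
                poisson_counts[name] = counts
                pop = self.populations[dev.target.population]
                np.add.at(pop.i_syn, np.asarray(dev.target.indices),
                          counts * dev.weight)
            elif isinstance(dev, DCGeneratorDevice):
                pop = self.populations[dev.target.population]
                np.add.at(pop.i_ext, np.asarray(dev.target.indices), dev.amplitude)

        t_spike = self.time_ms + dt
        spiked: dict[str, np.ndarray] = {}
        records: list[SpikeRecord] = []

        # 3. integrate + threshold
        for pop in self.populations.values():
            p = pop.params
            active = pop.refrac <= 0
            i_total = pop.i_syn + pop.i_ext
            v_inf = p.v_rest + p.r_m * i_total
            decay = np.exp(-dt / p.tau_m)
            pop.v = np.where(active, v_inf + (pop.v - v_inf) * decay, p.v_reset)
            pop.i_syn *= np.exp(-dt / p.tau_syn)
            pop.refrac = np.maximum(pop.refrac - dt, 0.0)

            if not np.all(np.isfinite(pop.v)):
                raise SimulationFault(
                    f"non-finite membrane potential in population {pop.name!r}")

            fired = np.flatnonzero(active & (pop.v >= p.v_thresh))
            if fired.size:
                pop.v[fired] = p.v_reset
                pop.refrac[fired] = p.tau_refrac
                spiked[pop.name] = fired
                records.extend(
                    SpikeRecord(int(pop.offset + i), t_spike) for i in fired)

        # 4. queue synaptic events through projections
        for proj in self.projections:
            fired = spiked.get(proj.pre.population)
            if fired is None:
                continue
            pre_idx = np.asarray(proj.pre.indices)
            hit = np.isin(pre_idx, fired)
            if not hit.any():
                continue
            contrib = proj.weights[hit, :].sum(axis=0)
            delay_steps = max(1, int(np.ceil(proj.delay_ms / self.dt_ms - 1e-9)))
            slot = self._queue.setdefault(self.step_index + delay_steps, {})
            acc = slot.setdefault(proj.post.population,
                                  np.zeros(self.populations[proj.post.population].size))
            np.add.at(acc, np.asarray(proj.post.indices), contrib)

        # 5. output devices
        for dev in self.devices.values():
            if isinstance(dev, LeakyIntegratorDevice):
                dev.decay(dt)
                fired = spiked.get(dev.target.population)
                if fired is not None:
                    n = int(np.isin(np.asarray(dev.target.indices), fired).sum())
                    if n:
                        dev.add_spikes(n)
            elif isinstance(dev, SpikeRecorderDevice):
                fired = spiked.get(dev.target.population)
                if fired is not None:
                    tgt = np.asarray(dev.target.indices)
                    mine = tgt[np.isin(tgt, fired)]
                    if mine.size:
                        off = self.populations[dev.target.population].offset
                        dev.record(t_spike, off + mine)
            elif isinstance(dev, PopulationRateDevice):
                fired = spiked.get(dev.target.population)
                if fired is not None:
                    n = int(np.isin(np.asarray(dev.target.indices), fired).sum())
                    dev.record(t_spike, n)

        self.time_ms = t_spike
        self.step_index += 1
        self.spike_log.extend(records)
        return records

    def run(self, duration_ms: float) -> list[SpikeRecord]:
        n = int(round(duration_ms / self.dt_ms))
        out: list[SpikeRecord] = []
        for _ in range(n):
            out.extend(self.step())
        return out


def build_network(description: dict, dt_ms: float = 1.0) -> Network:
    """Build a Network from a declarative description.

    Description schema::

        {"populations": [{"name": str, "size": int, "params": {...}}, ...],
         "projections": [{"pre": ref, "post": ref,
                          "weight": scalar | matrix, "delay_ms": float}, ...],
         "index_sets": {name: {"population": str, "indices": [...]}},
         "devices": {name: {"kind": str, "target": ref, "params": {...}}}}

    References may be population names, index-set names, or
    {"population", "indices"} dicts. Overlapping index sets are allowed and
    alias the same neurons. An empty description yields an empty network.
    """
    net = Network(dt_ms=dt_ms)
    for pd in description.get("populations", []):
        params = LIFParams(**pd["params"]) if pd.get("params") else None
        net.add_population(pd["name"], pd["size"], params)
    for name, sd in description.get("index_sets", {}).items():
        net.define_index_set(name, sd["population"], sd["indices"])
    for pj in description.get("projections", []):
        net.connect(pj["pre"], pj["post"], pj.get("weight", pj.get("weights", 0.0)),
                    pj.get("delay_ms", 1.0))
    for name, dd in description.get("devices", {}).items():
        net.attach_device(name, DeviceSpec(kind=dd["kind"], target=dd.get("target"),
                                           params=dd.get("params", {})))
    return net


def spikes_to_csv(records: list[SpikeRecord]) -> str:
    """Render spike records as CSV text with columns ``time_ms,neuron_id``."""
    lines = ["time_ms,neuron_id"]
    lines.extend(f"{r.time_ms:g},{r.neuron_id}" for r in records)
    return "\n".join(lines) + "\n"
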