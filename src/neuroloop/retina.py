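"""Retina processing chain for color-opponent visual tracking.

A microcircuit-style retina model used as a robot-to-neuron stage: a
(space-variant) Gaussian spatial filter, a temporal low-pass filter, a
single-compartment leaky accumulator, a configurable static nonlinearity,
and a short-term plasticity (STP) resource — composed into two red-green
opponent pathways. Pathway outputs are analog per-pixel currents (the
presynaptic currents of model ganglion cells); a horizontal stripe of
those currents drives a two-layer spiking readout whose second-layer spike
counts are decoded into the horizontal position (centroid) of a colored
target.

Opponency composition (declared, and mirrored between pathways): for the
green-ON/red-OFF pathway, the center signal is the green channel passed
through the temporal low-pass, a narrow Gaussian and the STP resource; the
surround is the red channel under a wider Gaussian; center excites and
surround inhibits a single-compartment accumulator whose rectified
potential is the pathway output. The STP resource is what makes each
pathway *history dependent*: sustained drive on the center channel
depletes it, so a green stimulus landing on a region previously free of
green (e.g., one that was red) meets a recovered resource and evokes a
larger response than the same stimulus after a gray history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spiking import DeviceSpec, LIFParams, Network

__all__ = [
    "SpatialFilterConfig",
    "TemporalLowpass",
    "SingleCompartment",
    "NonlinearityConfig",
    "apply_nonlinearity",
    "ShortTermPlasticity",
    "RetinaPathway",
    "RedGreenOpponency",
    "OpponencyOutput",
    "gaussian_filter",
    "extract_stripe",
    "build_retina_brain",
    "centroid_from_spikes",
    "eye_command",
    "pixel_bearing",
    "RetinaConfig",
]


# ---------------------------------------------------------------------------
# Microcircuits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialFilterConfig:
    """Gaussian blur width in pixels: a scalar, a per-axis (sigma_row,
    sigma_col) pair for anisotropic receptive fields, or a per-pixel sigma
    map for a space-variant filter."""

    sigma: object = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if np.any(s < 0):
            raise ValueError("sigma must be >= 0 everywhere")


def gaussian_filter(channel: np.ndarray, config: SpatialFilterConfig) -> np.ndarray:
    """Normalized Gaussian blur, optionally space-variant.

    With a scalar sigma this is a standard separable Gaussian (nearest-edge
    padding, kernel normalized so a constant map is preserved exactly).
    With a per-pixel sigma map, the map is blurred once per distinct sigma
    value and each output pixel takes the result for its local sigma — an
    exact space-variant filter when the sigma map is piecewise constant.
    """
    channel = np.asarray(channel, dtype=float)
    sigma = np.asarray(config.sigma, dtype=float)
    if sigma.ndim == 0:
        s = float(sigma)
        if s == 0:
            return channel.copy()
        return ndimage.gaussian_filter(channel, sigma=s, mode="nearest")
    if sigma.ndim == 1:  # per-axis (rows, cols)
        if np.all(sigma == 0):
            return channel.copy()
        return ndimage.gaussian_filter(channel, sigma=tuple(sigma), mode="nearest")
    if sigma.shape != channel.shape:
        raise ValueError("sigma map must match channel shape")
    out = np.empty_like(channel)
    for s in np.unique(sigma):
        mask = sigma == s
        blurred = channel.copy() if s == 0 else ndimage.gaussian_filter(
            channel, sigma=float(s), mode="nearest")
        out[mask] = blurred[mask]
    return out


class TemporalLowpass:
    """First-order low-pass: y <- y + (dt/tau) * (x - y), per pixel."""

    def __init__(self, tau_ms: float = 50.0, shape=None):
        if tau_ms <= 0:
            raise ValueError("tau must be > 0")
        self.tau_ms = float(tau_ms)
        self.y = None if shape is None else np.zeros(shape)

    def step(self, x: np.ndarray, dt_ms: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.y is None:
            self.y = np.zeros_like(x)
        self.y = self.y + (dt_ms / self.tau_ms) * (x - self.y)
        return self.y

    def reset(self) -> None:
        self.y = None


class SingleCompartment:
    """Leaky accumulator: v <- v + (dt/tau) * (-v + g_e*E - g_i*I)."""

    def __init__(self, tau_ms: float = 20.0, g_e: float = 1.0, g_i: float = 1.0):
        if tau_ms <= 0:
            raise ValueError("tau must be > 0")
        self.tau_ms, self.g_e, self.g_i = float(tau_ms), float(g_e), float(g_i)
        self.v = None

    def step(self, excitatory, inhibitory, dt_ms: float) -> np.ndarray:
        e = np.asarray(excitatory, dtype=float)
        i = np.asarray(inhibitory, dtype=float)
        if self.v is None:
            self.v = np.zeros_like(e)
        self.v = self.v + (dt_ms / self.tau_ms) * (
            -self.v + self.g_e * e - self.g_i * i)
        return self.v

    def reset(self) -> None:
        self.v = None


@dataclass(frozen=True)
class NonlinearityConfig:
    """Static elementwise nonlinearity; all kinds are monotone non-decreasing.

    identity: x; rectifier: gain * max(0, x - offset);
    sigmoid: 1 / (1 + exp(-gain * (x - offset))).
    """

    kind: str = "identity"
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "rectifier", "sigmoid"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        if self.gain < 0:
            raise ValueError("gain must be >= 0 (monotone non-decreasing map)")


def apply_nonlinearity(x: np.ndarray, config: NonlinearityConfig) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if config.kind == "identity":
        return x
    if config.kind == "rectifier":
        return config.gain * np.maximum(0.0, x - config.offset)
    return 1.0 / (1.0 + np.exp(-config.gain * (x - config.offset)))


class ShortTermPlasticity:
    """Depressing synaptic resource x in [0, 1] gating its input.

    output = x * u;  dx/dt = (1 - x)/tau_rec - depression * x * u.
    Sustained input depletes the resource toward a steady state below 1;
    silence lets it recover toward 1 with ``tau_rec``.
    """

    def __init__(self, depression: float = 0.02, tau_rec_ms: float = 500.0):
        if tau_rec_ms <= 0:
            raise ValueError("recovery tau must be > 0")
        if depression < 0:
            raise ValueError("depression rate must be >= 0")
        self.depression = float(depression)
        self.tau_rec_ms = float(tau_rec_ms)
        self.x = None

    def step(self, u, dt_ms: float) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.x is None:
            self.x = np.ones_like(u)
        out = self.x * u
        self.x = self.x + dt_ms * ((1.0 - self.x) / self.tau_rec_ms
                                   - self.depression * self.x * u)
        self.x = np.clip(self.x, 0.0, 1.0)
        return out

    def reset(self) -> None:
        self.x = None


# ---------------------------------------------------------------------------
# Opponency pathways
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetinaConfig:
    """Declared defaults for the opponency chain (all values are model
    parameters of this artifact; widths in pixels, times in ms)."""

    center_sigma: object = 1.0
    surround_sigma: object = 4.0  # scalar or per-axis (rows, cols)
    lowpass_tau_ms: float = 50.0
    compartment_tau_ms: float = 20.0
    g_e: float = 1.0
    g_i: float = 0.5
    stp_depression: float = 0.02
    stp_tau_rec_ms: float = 500.0
    nonlinearity: NonlinearityConfig = field(
        default_factory=lambda: NonlinearityConfig("rectifier", gain=1.0,
                                                   offset=0.02))


@dataclass(frozen=True)
class OpponencyOutput:
    """Per-pixel output currents (nA) of the two opponent pathways."""

    green_on: np.ndarray   # G+R- pathway
    red_on: np.ndarray     # R+G- pathway


class RetinaPathway:
    """One opponent pathway: center channel ON, surround channel OFF."""

    def __init__(self, center_channel: int, surround_channel: int,
                 config: RetinaConfig = RetinaConfig()):
        self.center_channel = center_channel
        self.surround_channel = surround_channel
        self.config = config
        self.lowpass = TemporalLowpass(config.lowpass_tau_ms)
        self.stp = ShortTermPlasticity(config.stp_depression, config.stp_tau_rec_ms)
        self.compartment = SingleCompartment(config.compartment_tau_ms,
                                             config.g_e, config.g_i)

    def step(self, frame: np.ndarray, dt_ms: float) -> np.ndarray:
        """Process one RGB frame (float in [0,1], shape (H, W, 3))."""
        cfg = self.config
        center_raw = frame[..., self.center_channel]
        surround_raw = frame[..., self.surround_channel]
        center = gaussian_filter(self.lowpass.step(center_raw, dt_ms),
                                 SpatialFilterConfig(cfg.center_sigma))
        center = self.stp.step(center, dt_ms)
        surround = gaussian_filter(surround_raw,
                                   SpatialFilterConfig(cfg.surround_sigma))
        v = self.compartment.step(center, surround, dt_ms)
        return apply_nonlinearity(v, cfg.nonlinearity)

    def reset(self) -> None:
        self.lowpass.reset()
        self.stp.reset()
        self.compartment.reset()


class RedGreenOpponency:
    """The two mirrored opponent pathways over an RGB frame stream."""

    def __init__(self, config: RetinaConfig = RetinaConfig()):
        self.config = config
        self.green_on = RetinaPathway(center_channel=1, surround_channel=0,
                                      config=config)
        self.red_on = RetinaPathway(center_channel=0, surround_channel=1,
                                    config=config)

    def step(self, frame: np.ndarray, dt_ms: float) -> OpponencyOutput:
        raw = np.asarray(frame)
        if raw.dtype == np.uint8:  # accept 8-bit camera images
            frame = raw.astype(float) / 255.0
        else:
            frame = raw.astype(float)
        return OpponencyOutput(green_on=self.green_on.step(frame, dt_ms),
                               red_on=self.red_on.step(frame, dt_ms))

    def reset(self) -> None:
        self.green_on.reset()
        self.red_on.reset()


def extract_stripe(output: OpponencyOutput, row: int) -> np.ndarray:
    """One horizontal stripe of both pathway outputs, stacked.

    Returns an array of shape (2, width): row 0 the green-ON pathway, row 1
    the red-ON pathway, at the requested image row.
    """
    h = output.green_on.shape[0]
    if not (0 <= row < h):
        raise ValueError(f"row {row} outside image of height {h}")
    return np.stack([output.green_on[row], output.red_on[row]])


# ---------------------------------------------------------------------------
# Spiking readout
# ---------------------------------------------------------------------------

def build_retina_brain(width: int = 320, fan_in: int = 7,
                       w2: float = 0.8, delay_ms: float = 1.0,
                       params: LIFParams | None = None) -> Network:
    """Two-layer spiking readout for the retinal stripe.

    Layer 1 (2*width neurons: one per pathway and stripe pixel) converts
    injected retinal currents to spikes. Each layer-2 neuron integrates a
    ``fan_in``-neuron window of its own pathway's layer-1 row (stride 1,
    windows truncated at the edges), acting as a local spike integrator
    whose activity concentrates at the target edges. With the default
    320-pixel stripe the network totals 1,280 neurons.

    Devices: ``retina_currents`` (DC injection into layer 1, one amplitude
    per neuron) and ``layer2_spikes`` (spike recorder on layer 2).
    """
    net = Network(dt_ms=1.0)
    p = params or LIFParams()
    net.add_population("layer1", 2 * width, p)
    net.add_population("layer2", 2 * width, p)
    half = fan_in // 2
    weights = np.zeros((2 * width, 2 * width))
    for pathway in range(2):
        base = pathway * width
        for i in range(width):
            lo, hi = max(0, i - half), min(width - 1, i + half)
            weights[base + lo: base + hi + 1, base + i] = w2
    net.connect("layer1", "layer2", weights, delay_ms=delay_ms)
    net.attach_device("retina_currents",
                      DeviceSpec("dc_generator", target="layer1"))
    net.attach_device("layer2_spikes",
                      DeviceSpec("spike_recorder", target="layer2"))
    net.define_index_set("layer1", "layer1", range(2 * width))
    net.define_index_set("layer2", "layer2", range(2 * width))
    return net


def retina_brain_description(width: int = 320, fan_in: int = 7,
                             w2: float = 0.8) -> dict:
    """The same two-layer readout as a declarative brain description."""
    half = fan_in // 2
    weights = np.zeros((2 * width, 2 * width))
    for pathway in range(2):
        base = pathway * width
        for i in range(width):
            lo, hi = max(0, i - half), min(width - 1, i + half)
            weights[base + lo: base + hi + 1, base + i] = w2
    return {
        "populations": [{"name": "layer1", "size": 2 * width},
                        {"name": "layer2", "size": 2 * width}],
        "projections": [{"pre": "layer1", "post": "layer2",
                         "weight": weights, "delay_ms": 1.0}],
        "devices": {
            "retina_currents": {"kind": "dc_generator", "target": "layer1"},
            "layer2_spikes": {"kind": "spike_recorder", "target": "layer2"},
        },
    }


def centroid_from_spikes(counts: np.ndarray, width: int | None = None,
                         min_spikes: int = 3) -> float | None:
    """Spike-count-weighted mean stripe pixel across both pathway maps.

    ``counts`` is the per-neuron layer-2 spike count over a trailing
    window, laid out as the two stacked pathway rows (length 2*width or
    shape (2, width)). Returns the centroid pixel position, or None when
    the total count is below ``min_spikes`` (no detectable target).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        if width is None:
            width = counts.size // 2
        counts = counts.reshape(2, width)
    per_pixel = counts.sum(axis=0)
    total = per_pixel.sum()
    if total < min_spikes:
        return None
    pixels = np.arange(per_pixel.size)
    return float(np.dot(per_pixel, pixels) / total)


def pixel_bearing(pixel: float, width: int, fov_rad: float) -> float:
    """Bearing of a pixel column, positive to the right of image center."""
    return (pixel / (width - 1) - 0.5) * fov_rad


def eye_command(centroid_px: float | None, width: int, fov_rad: float,
                k_p: float = 4.0, max_omega: float = 2.0) -> float:
    """Proportional eye velocity toward the centroid's bearing (rad/s).

    Positive command means "rotate toward the right of the image". An
    absent centroid yields a zero command (hold). The command saturates at
    ``max_omega``.
    """
    if centroid_px is None:
        return 0.0
    omega = k_p * pixel_bearing(centroid_px, width, fov_rad)
    return float(np.clip(omega, -max_omega, max_omega))
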