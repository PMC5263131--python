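"""Deterministic 2D world simulator.

Provides the robot bodies (differential-drive base with a pan-mounted
camera, 3-DOF planar arm), environments made of colored screens, a
synthetic raycast camera, and a publish/subscribe topic bus that stands in
for robotics middleware.

Conventions: meters, right-handed coordinates, heading theta = 0 along +x
and increasing counterclockwise, wrapped to (-pi, pi]. Images are RGB
uint8, row-major, origin top-left.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pose2D",
    "Camera",
    "DifferentialDriveRobot",
    "PlanarArm",
    "Screen",
    "CameraImage",
    "TopicBus",
    "World",
    "arm_forward_kinematics",
    "wrap_angle",
    "WorldError",
]

BACKGROUND_COLOR = (128, 128, 128)  # mid-gray


class WorldError(ValueError):
    """Invalid world configuration or command."""


def wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]; exact no-op when already in range."""
    if -np.pi < theta <= np.pi:
        return float(theta)
    t = (theta + np.pi) % (2.0 * np.pi) - np.pi
    return float(np.pi) if t == -np.pi else float(t)


@dataclass
class Pose2D:
    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.theta])):
            raise WorldError("pose must be finite")
        self.theta = wrap_angle(self.theta)


@dataclass
class Camera:
    """Horizontal-scan camera: one ray per pixel column across the FOV."""

    width: int = 64
    height: int = 64
    fov_rad: float = np.pi / 2
    pan_rad: float = 0.0  # yaw offset relative to the carrying body

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise WorldError("camera resolution must be >= 1x1")
        if not (0 < self.fov_rad < np.pi):
            raise WorldError("camera fov must be in (0, pi)")


@dataclass
class DifferentialDriveRobot:
    """Differential-drive base; wheel speeds in m/s, track width in m."""

    pose: Pose2D = field(default_factory=Pose2D)
    track_width: float = 0.4
    vl: float = 0.0
    vr: float = 0.0
    camera: Camera = field(default_factory=Camera)

    def __post_init__(self) -> None:
        if self.track_width <= 0:
            raise WorldError("track width must be > 0")


@dataclass
class PlanarArm:
    """Serial planar revolute chain. Angles rad, link lengths m."""

    lengths: tuple[float, ...] = (0.3, 0.25, 0.15)
    angles: np.ndarray = None
    limits: tuple[tuple[float, float], ...] = None
    velocities: np.ndarray = None  # commanded joint velocities, rad/s

    def __post_init__(self) -> None:
        n = len(self.lengths)
        if self.angles is None:
            self.angles = np.zeros(n)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.limits is None:
            self.limits = tuple((-np.pi, np.pi) for _ in range(n))
        if self.velocities is None:
            self.velocities = np.zeros(n)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if len(self.angles) != n or len(self.limits) != n:
            raise WorldError("arm angles/limits must match link count")
        self.clip_to_limits()

    def clip_to_limits(self) -> None:
        lo = np.array([l for l, _ in self.limits])
        hi = np.array([h for _, h in self.limits])
        self.angles = np.clip(self.angles, lo, hi)

    def tcp(self) -> np.ndarray:
        return arm_forward_kinematics(self.angles, self.lengths)


def arm_forward_kinematics(angles, lengths) -> np.ndarray:
    """Tool-center-point position of a planar serial chain.

    Standard planar FK: link i points along the cumulative sum of the first
    i joint angles; the TCP is the vector sum of the links.
    """
    angles = np.asarray(angles, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if angles.shape != lengths.shape:
        raise WorldError("angles and lengths must have the same length")
    phi = np.cumsum(angles)
    return np.array([np.sum(lengths * np.cos(phi)), np.sum(lengths * np.sin(phi))])


@dataclass
class Screen:
    """A colored billboard segment in the world.

    The screen is a segment of length ``width`` centered at ``center``,
    running along direction ``orientation`` (rad; the default pi/2 makes a
    screen placed on the +x axis face a robot at the origin). ``height``
    controls the apparent vertical extent. The displayed content is either
    a solid ``color`` or, when ``target_u`` is set, a circle of
    ``target_color`` at horizontal fraction ``target_u`` in [0, 1] over the
    solid background — the controllable stimulus for tracking scenarios.
    """

    id: str
    center: tuple[float, float]
    width: float = 1.0
    color: tuple[int, int, int] = (0, 0, 255)
    height: float = None
    orientation: float = np.pi / 2
    target_u: float = None
    target_color: tuple[int, int, int] = (0, 255, 0)
    target_radius: float = 0.05  # as a fraction of screen width

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise WorldError(f"screen {self.id!r}: width must be > 0")
        if self.height is None:
            self.height = self.width

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.array([np.cos(self.orientation), np.sin(self.orientation)])
        c = np.asarray(self.center, dtype=float)
        return c - 0.5 * self.width * d, c + 0.5 * self.width * d

    def sample(self, u: float, v: float) -> tuple[int, int, int]:
        """Color at horizontal fraction u and vertical fraction v (0..1)."""
        if self.target_u is not None:
            r = self.target_radius
            if (u - self.target_u) ** 2 + (v - 0.5) ** 2 <= r * r:
                return self.target_color
        return self.color


@dataclass(frozen=True)
class CameraImage:
    """RGB image; ``pixels`` is a (height, width, 3) uint8 array."""

    width: int
    height: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.height, self.width, 3):
            raise WorldError("pixel array shape mismatch")


class TopicBus:
    """Latest-value publish/subscribe channels with per-topic FIFO history.

    Publishing never blocks; within one step the last writer wins for the
    latest value, while the history preserves publication order.
    """

    def __init__(self) -> None:
        self._latest: dict[str, object] = {}
        self._history: dict[str, list[object]] = {}

    def publish(self, topic: str, message) -> None:
        self._latest[topic] = message
        self._history.setdefault(topic, []).append(message)

    def read(self, topic: str, default=None):
        return self._latest.get(topic, default)

    def history(self, topic: str) -> list:
        return list(self._history.get(topic, ()))

    def topics(self) -> list[str]:
        return sorted(self._latest)


class World:
    """The simulated world: bodies, screens, bus, and a fixed-step clock."""

    def __init__(self, robot: DifferentialDriveRobot | None = None,
                 arm: PlanarArm | None = None,
                 screens: list[Screen] | None = None,
                 background: tuple[int, int, int] = BACKGROUND_COLOR) -> None:
        self.robot = robot if robot is not None else DifferentialDriveRobot()
        self.arm = arm
        self.screens: dict[str, Screen] = {}
        for s in screens or []:
            if s.id in self.screens:
                raise WorldError(f"duplicate screen id {s.id!r}")
            self.screens[s.id] = s
        self.background = background
        self.bus = TopicBus()
        self.time_ms = 0.0
        self._initial = None
        self.snapshot_initial()

    def snapshot_initial(self) -> None:
        """Record the state reset() restores: pose, arm, screens."""
        self._initial = {
            "pose": copy.deepcopy(self.robot.pose),
            "pan": self.robot.camera.pan_rad,
            "arm_angles": None if self.arm is None else self.arm.angles.copy(),
            "screens": copy.deepcopy(self.screens),
        }

    # -- commands ---------------------------------------------------------

    def set_wheel_speeds(self, vl: float, vr: float) -> None:
        if not np.all(np.isfinite([vl, vr])):
            raise WorldError("wheel speeds must be finite")
        self.robot.vl, self.robot.vr = float(vl), float(vr)

    def set_pan_velocity(self, omega: float) -> None:
        if not np.isfinite(omega):
            raise WorldError("pan velocity must be finite")
        self._pan_velocity = float(omega)

    def set_screen_color(self, screen_id: str, color) -> None:
        if screen_id not in self.screens:
            raise WorldError(f"unknown screen {screen_id!r}")
        self.screens[screen_id].color = tuple(int(c) for c in color)

    def set_screen_target(self, screen_id: str, u: float | None) -> None:
        if screen_id not in self.screens:
            raise WorldError(f"unknown screen {screen_id!r}")
        self.screens[screen_id].target_u = None if u is None else float(u)

    def set_arm_angles(self, angles) -> None:
        if self.arm is None:
            raise WorldError("world has no arm")
        self.arm.angles = np.asarray(angles, dtype=float)
        self.arm.clip_to_limits()

    def apply_command(self, topic: str, message) -> None:
        """Apply a published command message to the corresponding actuator.

        Registered command topics: ``cmd/wheels`` (vl, vr), ``cmd/pan_vel``
        (rad/s), ``cmd/arm_angles`` (joint vector), ``cmd/arm_velocities``.
        """
        if topic == "cmd/wheels":
            try:
                vl, vr = message
            except (TypeError, ValueError):
                raise WorldError(f"cmd/wheels expects (vl, vr), got {message!r}")
            self.set_wheel_speeds(vl, vr)
        elif topic == "cmd/pan_vel":
            self.set_pan_velocity(float(message))
        elif topic == "cmd/arm_angles":
            self.set_arm_angles(message)
        elif topic == "cmd/screen_target":
            try:
                screen_id, u = message
            except (TypeError, ValueError):
                raise WorldError(
                    f"cmd/screen_target expects (screen_id, u), got {message!r}")
            self.set_screen_target(screen_id, u)
        elif topic == "cmd/arm_velocities":
            if self.arm is None:
                raise WorldError("world has no arm")
            v = np.asarray(message, dtype=float)
            if v.shape != self.arm.velocities.shape:
                raise WorldError("arm velocity vector has wrong length")
            self.arm.velocities = v
        else:
            raise WorldError(f"unknown command topic {topic!r}")

    # -- dynamics ---------------------------------------------------------

    _pan_velocity: float = 0.0

    def step(self, dt_ms: float) -> None:
        """Advance the world by one step of closed-form unicycle kinematics.

        Arc motion is integrated exactly (not Euler), so two steps of dt
        compose to one step of 2*dt under constant commands.
        """
        if dt_ms <= 0:
            raise WorldError("dt must be > 0")
        dt = dt_ms / 1000.0
        r = self.robot
        v = 0.5 * (r.vl + r.vr)
        omega = (r.vr - r.vl) / r.track_width
        th = r.pose.theta
        if abs(omega) < 1e-12:
            r.pose.x += v * dt * np.cos(th)
            r.pose.y += v * dt * np.sin(th)
        else:
            r.pose.x += (v / omega) * (np.sin(th + omega * dt) - np.sin(th))
            r.pose.y += (v / omega) * (-np.cos(th + omega * dt) + np.cos(th))
            r.pose.theta = wrap_angle(th + omega * dt)
        r.camera.pan_rad += self._pan_velocity * dt
        if self.arm is not None:
            self.arm.angles = self.arm.angles + self.arm.velocities * dt
            self.arm.clip_to_limits()
        self.time_ms += dt_ms
        self.publish_sensors()

    def publish_sensors(self) -> None:
        """Republish all sensor topics from the current state."""
        r = self.robot
        self.bus.publish("sensor/pose", (r.pose.x, r.pose.y, r.pose.theta))
        self.bus.publish("sensor/pan", r.camera.pan_rad)
        self.bus.publish("sensor/camera", self.render_camera())
        if self.arm is not None:
            self.bus.publish("sensor/arm_angles", self.arm.angles.copy())
            self.bus.publish("sensor/tcp", self.arm.tcp())

    def reset_robot_pose(self) -> None:
        """Restore the initial pose; zero velocities. Screens untouched."""
        self.robot.pose = copy.deepcopy(self._initial["pose"])
        self.robot.camera.pan_rad = self._initial["pan"]
        self.robot.vl = self.robot.vr = 0.0
        self._pan_velocity = 0.0
        if self.arm is not None and self._initial["arm_angles"] is not None:
            self.arm.angles = self._initial["arm_angles"].copy()
            self.arm.velocities = np.zeros_like(self.arm.velocities)

    def reset_environment(self) -> None:
        """Restore screens (colors, targets) to their initial description."""
        self.screens = copy.deepcopy(self._initial["screens"])

    # -- camera -----------------------------------------------------------

    def render_camera(self) -> CameraImage:
        """Raycast render: one ray per pixel column across the horizontal FOV.

        Each column's ray starts at the robot position with bearing
        heading + pan + column angle (leftmost column = +fov/2). The nearest
        intersected screen supplies the column color, sampled from the
        screen pattern; the vertical fill is the screen's apparent angular
        height at the hit distance. Screens behind the robot are culled by
        the ray parameterization (t > 0 only).
        """
        cam = self.robot.camera
        W, H = cam.width, cam.height
        img = np.empty((H, W, 3), dtype=np.uint8)
        img[:, :] = self.background
        origin = np.array([self.robot.pose.x, self.robot.pose.y])
        base = self.robot.pose.theta + cam.pan_rad
        # column bearings, leftmost pixel at +fov/2
        cols = base + cam.fov_rad * (0.5 - (np.arange(W) + 0.5) / W)
        dirs = np.stack([np.cos(cols), np.sin(cols)], axis=1)
        vfov = cam.fov_rad * H / W

        segs = []
        for s in self.screens.values():
            a, b = s.endpoints()
            segs.append((s, a, b - a))

        for j in range(W):
            d = dirs[j]
            best_t, best = np.inf, None
            for s, a, ab in segs:
                # solve origin + t*d = a + u*ab  (Cramer on [d, -ab])
                det = -d[0] * ab[1] + ab[0] * d[1]
                if abs(det) < 1e-12:
                    continue
                rhs = a - origin
                t = (-rhs[0] * ab[1] + ab[0] * rhs[1]) / det
                u = (d[0] * rhs[1] - d[1] * rhs[0]) / det
                if t > 1e-9 and 0.0 <= u <= 1.0 and t < best_t:
                    best_t, best = t, (s, u)
            if best is None:
                continue
            s, u = best
            half_angle = np.arctan2(0.5 * s.height, best_t)
            frac = min(1.0, 2.0 * half_angle / vfov)
            n_rows = int(round(frac * H))
            if n_rows <= 0:
                continue
            r0 = (H - n_rows) // 2
            for i in range(r0, r0 + n_rows):
                v = (i - r0 + 0.5) / n_rows
                img[i, j] = s.sample(u, v)
        return CameraImage(W, H, img)
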