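"""Sensorimotor learning: motor babbling on a planar arm.

The robot learns a forward kinematic model — predicting the tool center
point (TCP) from the joint configuration — by alternating two phases every
iteration: a babbling phase that moves the arm to a random joint
configuration and feeds the observed (angles, TCP) pair to the learner,
and an evaluation phase that moves to another random configuration and
records the Euclidean distance between predicted and true TCP. The whole
experiment runs as a single robot-to-robot transfer function: no brain
network is involved.

The learner is incremental linear least squares on the trigonometric
tensor-product basis over the joint angles (all products of 1, cos(q_j),
sin(q_j) across joints). Planar revolute-chain forward kinematics is a sum
of cosines/sines of partial angle sums, which expands exactly into this
basis, so with noiseless observations the model becomes exact once the
informative samples outnumber the basis (3^n coefficients for n joints).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np

from ..cle import Simulation
from ..config import CLEConfig, ExperimentConfig

__all__ = ["ForwardModel", "PhaseMachine", "sensorimotor_config",
           "run_sensorimotor", "SensorimotorResult"]

ARM_LENGTHS = (0.30, 0.25, 0.15)
JOINT_LIMITS = ((-np.pi / 2, np.pi / 2),) * 3


class ForwardModel:
    """Incremental least squares on the trigonometric tensor basis.

    Maintains the normal-equation sufficient statistics A = sum(phi phi^T)
    and b = sum(phi y^T); predictions use the minimum-norm least-squares
    solution, so the untrained model predicts the zero map and duplicate
    consistent samples leave the fit unchanged.
    """

    def __init__(self, n_joints: int = 3):
        self.n_joints = int(n_joints)
        self.n_features = 3 ** self.n_joints
        self._A = np.zeros((self.n_features, self.n_features))
        self._b = np.zeros((self.n_features, 2))
        self._weights = None
        self.n_samples = 0

    def features(self, angles) -> np.ndarray:
        angles = np.asarray(angles, dtype=float)
        if angles.shape != (self.n_joints,):
            raise ValueError(f"expected {self.n_joints} joint angles")
        per_joint = [np.array([1.0, np.cos(q), np.sin(q)]) for q in angles]
        return reduce(np.outer, per_joint).ravel()

    def update(self, angles, tcp) -> "ForwardModel":
        phi = self.features(angles)
        y = np.asarray(tcp, dtype=float)
        self._A += np.outer(phi, phi)
        self._b += np.outer(phi, y)
        self._weights = None
        self.n_samples += 1
        return self

    def predict(self, angles) -> np.ndarray:
        if self._weights is None:
            self._weights = np.linalg.lstsq(self._A, self._b, rcond=None)[0]
        return self.features(angles) @ self._weights


@dataclass
class PhaseMachine:
    """Tracks the alternation between babbling and evaluation."""

    phase: str = "evaluate"
    iteration: int = 0

    def advance(self) -> str:
        if self.phase == "evaluate":
            self.phase = "babble"
        else:
            self.phase = "evaluate"
            self.iteration += 1
        return self.phase


def babble_tf(ctx) -> None:
    """robot2robot controller: babble / evaluate on alternating steps.

    Commands issued at step n take effect at step n+1 (the one-step-delay
    contract), so each call first consumes the observation produced by its
    previous command, then issues the next one. The evaluation error at
    iteration i is recorded with the model trained on i babble samples;
    iteration 0 is therefore the untrained (zero-map) baseline.
    """
    st = ctx.state
    if "model" not in st:
        st["model"] = ForwardModel(len(ctx.params["limits"]))
        st["machine"] = PhaseMachine()
        st["pending"] = None
    limits = np.asarray(ctx.params["limits"], dtype=float)

    def random_pose():
        return ctx.rng.uniform(limits[:, 0], limits[:, 1])

    angles = ctx.topics["sensor/arm_angles"]
    tcp = ctx.topics["sensor/tcp"]
    model: ForwardModel = st["model"]
    machine: PhaseMachine = st["machine"]

    if st["pending"] == "evaluate":
        err = float(np.linalg.norm(model.predict(angles) - tcp))
        ctx.monitor("tcp_error", err)
        ctx.monitor("iteration", machine.iteration)
        machine.advance()  # -> babble
        ctx.publish("cmd/arm_angles", random_pose())
        st["pending"] = "babble"
    elif st["pending"] == "babble":
        model.update(angles, tcp)
        machine.advance()  # -> evaluate
        ctx.publish("cmd/arm_angles", random_pose())
        st["pending"] = "evaluate"
    else:  # first call: command the first evaluation pose
        ctx.publish("cmd/arm_angles", random_pose())
        st["pending"] = "evaluate"


def sensorimotor_config(seed: int = 0) -> ExperimentConfig:
    """Packaged sensorimotor-learning configuration (3-DOF planar arm)."""
    return ExperimentConfig(
        name="sensorimotor",
        cle=CLEConfig(cle_dt_ms=20.0, neural_dt_ms=1.0, seed=seed),
        world={
            "robot": {"camera": {"width": 8, "height": 8, "fov_deg": 90}},
            "arm": {"lengths": list(ARM_LENGTHS),
                    "limits": [list(l) for l in JOINT_LIMITS]},
        },
        brain={},  # no brain model in this experiment
        tfs=[{"name": "babble", "kind": "robot2robot",
              "subscriptions": ["sensor/arm_angles", "sensor/tcp"],
              "publications": ["cmd/arm_angles"],
              "body": babble_tf,
              "params": {"limits": [list(l) for l in JOINT_LIMITS]}}],
        monitors=["tcp_error", "iteration"],
    )


@dataclass
class SensorimotorResult:
    sim: Simulation
    errors: np.ndarray      # per-iteration TCP prediction error (m)
    iterations: np.ndarray

    @property
    def monitor(self):
        return self.sim.monitor

    def error_at(self, iteration: int) -> float:
        idx = np.flatnonzero(self.iterations == iteration)
        if idx.size == 0:
            raise ValueError(f"iteration {iteration} was not evaluated")
        return float(self.errors[idx[0]])


def run_sensorimotor(iterations: int = 50, seed: int = 1,
                     config: ExperimentConfig | None = None
                     ) -> SensorimotorResult:
    """Run the babble/evaluate loop and return the per-iteration error curve.

    ``errors[i]`` is the TCP prediction error after i babble updates
    (i = 0 .. iterations), evaluated at an independent random pose.
    """
    cfg = config if config is not None else sensorimotor_config(seed=seed)
    sim = Simulation(cfg)
    sim.initialize()
    # first command lands at step 2; one evaluation every 2 steps after that
    duration = (2 * iterations + 4) * cfg.cle.cle_dt_ms
    sim.run(duration)
    mon = sim.monitor
    errors = mon.values("tcp_error")
    iters = mon.values("iteration").astype(int)
    keep = iters <= iterations
    return SensorimotorResult(sim=sim, errors=errors[keep],
                              iterations=iters[keep])
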