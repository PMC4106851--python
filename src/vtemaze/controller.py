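"""Five-module plastic neural controller with separated learning/dynamics pathways.

Each sensory or motor module holds two unit vectors per neuron:

* **state units** ``s`` mirror the raw sensor/motor signals and are the
  *only* quantities entering the Hebbian rule;
* **virtual units** ``v`` carry internally propagated signals between
  modules and determine behavior (the motor module's virtual unit *is*
  the motor command ``u``).

Weights between ordered module pairs j -> i follow a Hebbian rule with
forgetting,

    dW[j->i] = eta[j->i] * (s_i(t) - s_i(t - tau)) (outer) s_j(t)
               - zeta[j->i] * W[j->i],

so a connection strengthens when the presynaptic module's signal and the
postsynaptic module's signal *change* are simultaneously high. Virtual
units are driven by the mismatch e_j = v_j - s_j of the source modules,

    v_i = sigma( sum_j W[j->i] @ e_j ),      sigma(x) = 1/(1 + exp(-a x)),

except the reward module's virtual unit, which is pinned to 1 (the "ideal"
reward state the robot acts to approach). The separation keeps plasticity
(state pathway) independent of the internal dynamics (virtual pathway),
avoiding the runaway positive feedback of naive Hebbian loops.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .world import K_IR, SensorFrame

__all__ = [
    "MODULES",
    "MODULE_SIZES",
    "ALL_PAIRS",
    "MINIMAL_PAIRS",
    "ControllerParams",
    "HebbianController",
]

MODULES = ("tactile", "vision", "ir", "reward", "motor")
MODULE_SIZES = {"tactile": 32, "vision": 20, "ir": 6, "reward": 1, "motor": 1}

#: Canonical ordering of the 20 directed module pairs (source j, target i).
ALL_PAIRS = tuple((j, i) for j in MODULES for i in MODULES if j != i)

#: Task-sufficient topology: cue recognition (touch-vision, touch-motor),
#: wall avoidance (ir-motor) and the reward-vision-motor chain.
MINIMAL_PAIRS = frozenset([
    ("tactile", "vision"),
    ("ir", "motor"),
    ("tactile", "motor"),
    ("reward", "vision"),
    ("vision", "motor"),
])


@dataclass(frozen=True)
class ControllerParams:
    """The 49 evolvable scalars of the controller plus fixed constants.

    40 pair rates (eta, zeta per directed pair in :data:`ALL_PAIRS` order)
    + delta + tau + sigmoid slope + c per phase (2) + V + 3 proportional
    input constants = 49. The IR proportional constant is fixed.
    """

    eta: dict[tuple[str, str], float]
    zeta: dict[tuple[str, str], float]
    delta: int = 10          # neural update period, environment steps, in [10, 30]
    tau: int = 1             # delayed-state lag, neural steps
    slope: float = 1.0       # sigmoid slope a (shared across modules)
    c_familiarization: float = 1.0  # motor conversion constant, familiarization
    c_maze: float = 1.0             # motor conversion constant, maze-solving
    v_forward: float = 2.0          # forward velocity V, cm per env step
    k_light: float = 1.0
    k_touch: float = 1.0
    k_reward: float = 1.0
    k_ir: float = K_IR       # fixed, not evolved
    normalize_inputs: bool = False  # 1/size_j normalization of incoming sums

    def __post_init__(self):
        if self.v_forward <= 0:
            raise ValueError("forward velocity must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1 neural step")
        if self.delta < 1:
            raise ValueError("delta must be >= 1 environment step")

    @classmethod
    def uniform(cls, eta: float = 0.1, zeta: float = 0.01,
                pairs=ALL_PAIRS, **kwargs) -> "ControllerParams":
        """Same learning/forgetting rate on every (enabled) pair."""
        return cls(eta={p: eta for p in pairs},
                   zeta={p: zeta for p in pairs}, **kwargs)

    def n_scalars(self) -> int:
        """Number of evolvable scalars represented (excludes fixed k_ir)."""
        # delta, tau, slope, c_fam, c_maze, V, k_light, k_touch, k_reward = 9
        return len(self.eta) + len(self.zeta) + 9  # full topology: 40 + 9 = 49

    def to_dict(self) -> dict:
        return {
            "eta": {f"{j}->{i}": v for (j, i), v in self.eta.items()},
            "zeta": {f"{j}->{i}": v for (j, i), v in self.zeta.items()},
            "delta": self.delta, "tau": self.tau, "slope": self.slope,
            "c_familiarization": self.c_familiarization, "c_maze": self.c_maze,
            "v_forward": self.v_forward, "k_light": self.k_light,
            "k_touch": self.k_touch, "k_reward": self.k_reward,
            "k_ir": self.k_ir, "normalize_inputs": self.normalize_inputs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerParams":
        def parse(rates):
            return {tuple(k.split("->")): float(v) for k, v in rates.items()}
        d = dict(d)
        return cls(eta=parse(d.pop("eta")), zeta=parse(d.pop("zeta")), **d)


class HebbianController:
    """The plastic controller; one :meth:`tick` per delta environment steps.

    Parameters
    ----------
    params :
        Decoded controller parameters.
    topology :
        ``"full"`` (all 20 directed pairs), ``"minimal"`` (the five
        task-sufficient pairs) or an explicit iterable of (source, target)
        pairs. Disabled pairs have no weight storage at all.
    """

    #: advertise to the trial runner that this controller consumes sensors
    needs_sensors = True

    def __init__(self, params: ControllerParams, topology="full"):
        self.params = params
        if topology == "full":
            pairs = ALL_PAIRS
        elif topology == "minimal":
            pairs = tuple(p for p in ALL_PAIRS if p in MINIMAL_PAIRS)
        else:
            pairs = tuple(tuple(p) for p in topology)
            unknown = [p for p in pairs if p not in ALL_PAIRS]
            if unknown:
                raise ValueError(f"unknown module pairs: {unknown}")
        missing = [p for p in pairs if p not in params.eta or p not in params.zeta]
        if missing:
            raise ValueError(f"params lack rates for enabled pairs: {missing}")
        self.pairs = pairs
        self.topology = topology if isinstance(topology, str) else "custom"
        self.learning = True
        self.reset_phase()

    # -- lifecycle -----------------------------------------------------------

    def reset_phase(self) -> None:
        """Zero all weights and virtual units (reward's v stays 1); clear history."""
        self.W = {
            (j, i): np.zeros((MODULE_SIZES[i], MODULE_SIZES[j]))
            for (j, i) in self.pairs
        }
        self.s = {m: np.zeros(MODULE_SIZES[m]) for m in MODULES}
        self.v = {m: np.zeros(MODULE_SIZES[m]) for m in MODULES}
        self.v["reward"][:] = 1.0
        self._history: deque[dict[str, np.ndarray]] = deque(maxlen=self.params.tau + 1)
        self.u = 0.5  # held motor output between ticks

    def copy_weights(self) -> dict:
        return {p: w.copy() for p, w in self.W.items()}

    def set_weights(self, weights: dict) -> None:
        for p in self.pairs:
            self.W[p][...] = weights[p]

    # -- the four per-tick stages ---------------------------------------------

    def set_states(self, frame: SensorFrame) -> None:
        """Stage 1: state units proportional to the raw signals; push history."""
        p = self.params
        if (len(frame.whiskers) != MODULE_SIZES["tactile"]
                or len(frame.camera) != MODULE_SIZES["vision"]
                or len(frame.ir) != MODULE_SIZES["ir"]):
            raise ValueError("sensor frame dimensionality mismatch")
        self.s["tactile"] = p.k_touch * np.asarray(frame.whiskers, dtype=float)
        self.s["vision"] = p.k_light * np.asarray(frame.camera, dtype=float)
        self.s["ir"] = np.asarray(frame.ir, dtype=float)  # k_ir already applied
        self.s["reward"] = np.array([p.k_reward * frame.reward], dtype=float)
        self.s["motor"] = np.array([self.u], dtype=float)
        self._history.append({m: self.s[m].copy() for m in MODULES})

    def _delayed_state(self, module: str) -> np.ndarray:
        """s(t - tau); zeros when the history is still shorter than tau."""
        if len(self._history) > self.params.tau:
            return self._history[-1 - self.params.tau][module]
        return np.zeros(MODULE_SIZES[module])

    def hebbian_update(self) -> None:
        """Stage 2: potentiate by (postsynaptic change) x (presynaptic state)."""
        p = self.params
        ds = {m: self.s[m] - self._delayed_state(m) for m in MODULES}
        for (j, i) in self.pairs:
            W = self.W[(j, i)]
            W += p.eta[(j, i)] * np.outer(ds[i], self.s[j]) - p.zeta[(j, i)] * W

    def virtual_update(self) -> None:
        """Stage 3: propagate mismatch signals; synchronous sigmoid update."""
        p = self.params
        e = {m: self.v[m] - self.s[m] for m in MODULES}
        new_v = {}
        for i in MODULES:
            if i == "reward":
                continue
            net = np.zeros(MODULE_SIZES[i])
            for (j, tgt) in self.pairs:
                if tgt != i:
                    continue
                contrib = self.W[(j, i)] @ e[j]
                if p.normalize_inputs:
                    contrib = contrib / MODULE_SIZES[j]
                net += contrib
            new_v[i] = expit(p.slope * net)
        for i, vi in new_v.items():
            self.v[i] = vi
        self.v["reward"][:] = 1.0

    def tick(self, frame: SensorFrame) -> float:
        """One neural step: set states, learn, propagate, emit motor output."""
        self.set_states(frame)
        if self.learning:
            self.hebbian_update()
        self.virtual_update()
        self.u = float(self.v["motor"][0])
        return self.u

    # -- trial-runner protocol -------------------------------------------------

    def observe_pose(self, pose) -> None:  # scripted policies use this; the
        pass                               # neural controller is sensor-driven

    def begin_trial(self, maze) -> None:
        pass

    def motor_constant(self, phase: str) -> float:
        return (self.params.c_familiarization if phase == "familiarization"
                else self.params.c_maze)
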