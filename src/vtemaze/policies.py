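"""Scripted policies: deterministic stand-ins for the neural controller.

These implement the same trial-runner protocol as
:class:`~vtemaze.controller.HebbianController` (``tick``, ``observe_pose``,
``reset_phase``, ``params``) but steer from ground-truth pose information.
They exist for testing and for protocol-level oracles (e.g. the fitness
ceiling of an always-successful policy); they are not models of anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .controller import ControllerParams
from .geometry import wrap_angle
from .world import Maze, RobotPose

__all__ = ["ScriptedPolicy", "OraclePolicy", "CirclingPolicy", "ZigzagPolicy",
           "ConstantPolicy", "policy_params"]


def policy_params(*, v_forward: float = 2.0, c_turn: float = 1.0,
                  delta: int = 1) -> ControllerParams:
    """Motion constants for scripted policies (no learning rates needed)."""
    return ControllerParams.uniform(
        eta=0.0, zeta=0.0, delta=delta, v_forward=v_forward,
        c_familiarization=c_turn, c_maze=c_turn,
    )


class ScriptedPolicy:
    """Base class: holds the held motor output and the motion constants."""

    needs_sensors = False

    def __init__(self, params: ControllerParams | None = None):
        self.params = params if params is not None else policy_params()
        self.u = 0.5

    def reset_phase(self) -> None:
        self.u = 0.5

    def observe_pose(self, pose: RobotPose) -> None:
        self._pose = pose

    def begin_trial(self, maze: Maze) -> None:
        self._maze = maze

    def motor_constant(self, phase: str) -> float:
        return (self.params.c_familiarization if phase == "familiarization"
                else self.params.c_maze)

    # learning flag is part of the runner protocol; scripted policies ignore it
    learning = False

    def tick(self, frame=None) -> float:
        raise NotImplementedError


class OraclePolicy(ScriptedPolicy):
    """Steers to the rewarded arm using the ground-truth maze state.

    Waypoint following: up the central arm to the junction center, then to
    the center of the reward zone. The turn command is proportional to the
    bearing error, clipped away from the extremes.
    """

    def __init__(self, params: ControllerParams | None = None, gain: float = 2.0):
        super().__init__(params)
        self.gain = gain

    def _waypoint(self) -> tuple[float, float]:
        cfg = self._maze.config
        pose = self._pose
        if pose.y < -cfg.half_cross_width + 2.0:  # still in the central arm
            return (0.0, 0.0)
        sx = -1.0 if cfg.reward_side == "left" else 1.0
        return (sx * (cfg.x_extent - cfg.reward_zone_depth / 2.0), 0.0)

    def tick(self, frame=None) -> float:
        wx, wy = self._waypoint()
        pose = self._pose
        bearing = math.atan2(wy - pose.y, wx - pose.x)
        err = float(wrap_angle(bearing - pose.heading))
        # err > 0 means the waypoint is to the left -> u > 0.5 (CCW turn)
        self.u = float(np.clip(0.5 + self.gain * err, 0.05, 0.95))
        return self.u


class CirclingPolicy(ScriptedPolicy):
    """Constant strong turn: circles inside the central arm until timeout."""

    def __init__(self, params: ControllerParams | None = None, u: float = 0.9):
        super().__init__(params)
        self._u_const = u

    def tick(self, frame=None) -> float:
        self.u = self._u_const
        return self.u


class ConstantPolicy(ScriptedPolicy):
    """Holds a fixed motor output forever."""

    def __init__(self, u: float, params: ControllerParams | None = None):
        super().__init__(params)
        self._u_const = u

    def tick(self, frame=None) -> float:
        self.u = self._u_const
        return self.u


class ZigzagPolicy(ScriptedPolicy):
    """Alternates between two motor outputs every ``period`` neural steps.

    With outputs symmetric around 0.5 this produces exactly one signed
    motor-output sign crossing per alternation, giving a known VTE count.
    """

    def __init__(self, params: ControllerParams | None = None, *,
                 u_high: float = 0.9, u_low: float = 0.1, period: int = 5):
        super().__init__(params)
        self.u_high, self.u_low, self.period = u_high, u_low, period
        self._n = 0

    def reset_phase(self) -> None:
        super().reset_phase()
        self._n = 0

    def tick(self, frame=None) -> float:
        self.u = self.u_high if (self._n // self.period) % 2 == 0 else self.u_low
        self._n += 1
        return self.u
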