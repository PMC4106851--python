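"""T-maze environment: geometry, differential-drive kinematics and sensors.

Coordinate convention: origin at the junction center, +y toward the cross
arm (the top of the T), headings in radians counter-clockwise from +x.
All lengths are in centimeters, scaled to the e-puck robot.

The robot carries four sensory channels:

* 32 binary whiskers (20 cm long, 16 per body side) that detect only the
  tactile cue post at the junction corner on the cued side;
* a 20-pixel omnidirectional camera in which only the black back wall of
  the cross arm renders as 1 (every other surface is white/transparent);
* 6 infrared proximity sensors on the front half of the body, reading
  k_IR * max(0, 1 - d/d_max);
* a reward channel that is +1 inside the reward zone, -1 inside the
  punishment zone and 0 elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .geometry import ray_segments_first_hit, segment_disc_intersects, wrap_angle

__all__ = [
    "RobotPose",
    "SensorFrame",
    "MazeConfig",
    "Maze",
    "step_kinematics",
    "ROBOT_RADIUS",
    "AXLE_WIDTH",
    "WHISKER_LENGTH",
    "N_WHISKERS",
    "N_PIXELS",
    "N_IR",
    "IR_RANGE",
    "K_IR",
]

ROBOT_RADIUS = 3.7     # cm, e-puck scale
AXLE_WIDTH = 5.3       # cm, wheel-to-wheel distance
WHISKER_LENGTH = 20.0  # cm
N_WHISKERS = 32
N_PIXELS = 20
N_IR = 6
IR_RANGE = 10.0        # cm, d_max of the proximity model
K_IR = 1.0             # fixed proportional constant of the IR channel

# Whisker mounting angles relative to heading: 16 fanned on each body side.
_LEFT_WHISKER_ANGLES = np.linspace(math.radians(20.0), math.radians(160.0), N_WHISKERS // 2)
_WHISKER_ANGLES = np.concatenate([_LEFT_WHISKER_ANGLES, -_LEFT_WHISKER_ANGLES])

# IR sensors uniformly over the front half of the body.
_IR_ANGLES = np.radians([-75.0, -45.0, -15.0, 15.0, 45.0, 75.0])


@dataclass(frozen=True)
class RobotPose:
    """Planar pose of the robot body center."""

    x: float
    y: float
    heading: float  # radians, CCW from +x

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.heading], dtype=float)


@dataclass(frozen=True)
class SensorFrame:
    """One tick of raw sensor readings."""

    whiskers: np.ndarray  # (32,) binary
    camera: np.ndarray    # (20,) in [0, 1]
    ir: np.ndarray        # (6,) >= 0
    reward: int           # -1, 0 or +1


@dataclass(frozen=True)
class MazeConfig:
    """T-maze geometry and trial protocol constants.

    The central arm runs along -y from the junction; the two cross arms run
    along +-x at the top. ``cue_side`` always equals ``reward_side``: the
    tactile post marks the rewarded arm.
    """

    central_arm_length: float = 120.0
    central_arm_width: float = 40.0
    cross_arm_length: float = 120.0   # per side, beyond the central corridor
    cross_arm_width: float = 40.0
    reward_side: Literal["left", "right"] = "left"
    reward_zone_depth: float = 10.0
    cue_radius: float = 2.0
    timeout_steps: int = 4000
    start_pose: RobotPose | None = None
    cue_active: bool = True
    reward_active: bool = True

    def __post_init__(self):
        for name in ("central_arm_length", "central_arm_width",
                     "cross_arm_length", "cross_arm_width", "reward_zone_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reward_side not in ("left", "right"):
            raise ValueError("reward_side must be 'left' or 'right'")
        if min(self.central_arm_width, self.cross_arm_width) < 2 * ROBOT_RADIUS:
            raise ValueError("corridor narrower than the robot body")
        if self.start_pose is None:
            object.__setattr__(self, "start_pose", self.default_start_pose())
        if not self.contains_disc(self.start_pose.x, self.start_pose.y, ROBOT_RADIUS):
            raise ValueError("start pose outside central arm free space")

    # ---- derived geometry -------------------------------------------------

    @property
    def cue_side(self) -> str:
        """The tactile cue is always on the rewarded side."""
        return self.reward_side

    @property
    def half_central_width(self) -> float:
        return self.central_arm_width / 2.0

    @property
    def half_cross_width(self) -> float:
        return self.cross_arm_width / 2.0

    @property
    def x_extent(self) -> float:
        """Half-width of the full cross corridor (junction center to arm end)."""
        return self.cross_arm_length + self.half_central_width

    @property
    def y_bottom(self) -> float:
        """y of the closed end of the central arm."""
        return -self.half_cross_width - self.central_arm_length

    @property
    def y_top(self) -> float:
        """y of the black back wall (top of the T)."""
        return self.half_cross_width

    def default_start_pose(self) -> RobotPose:
        """Centerline of the central arm, 10 cm from the closed end, facing the junction."""
        return RobotPose(0.0, self.y_bottom + 10.0, math.pi / 2.0)

    def cue_center(self) -> tuple[float, float]:
        sx = -1.0 if self.cue_side == "left" else 1.0
        return (sx * self.half_central_width, -self.half_cross_width)

    def walls(self) -> tuple[np.ndarray, np.ndarray, int]:
        """Boundary segments (a, b) and the index of the black back wall."""
        a = self.half_central_width
        b = self.x_extent
        c = -self.half_cross_width
        h = self.y_top
        y0 = self.y_bottom
        segs = [
            ((-b, h), (b, h)),      # 0: black back wall, top of the T
            ((b, c), (b, h)),       # right arm end
            ((-b, c), (-b, h)),     # left arm end
            ((a, c), (b, c)),       # cross-arm bottom, right of junction
            ((-b, c), (-a, c)),     # cross-arm bottom, left of junction
            ((a, y0), (a, c)),      # central arm right wall
            ((-a, y0), (-a, c)),    # central arm left wall
            ((-a, y0), (a, y0)),    # closed end
        ]
        pts = np.array(segs, dtype=float)
        return pts[:, 0, :], pts[:, 1, :], 0

    def wall_vertices(self) -> np.ndarray:
        a, b, _ = self.walls()
        return np.unique(np.vstack([a, b]), axis=0)

    # ---- free-space queries -----------------------------------------------

    def contains_point(self, x: float, y: float) -> bool:
        return self.contains_disc(x, y, 0.0)

    def contains_disc(self, x: float, y: float, r: float) -> bool:
        """True if a disc of radius r around (x, y) lies inside the free space.

        The free space is the union of the cross-corridor band and the
        central corridor; its complement inside the bounding box is two
        solid blocks flanking the central arm, so the test is the outer
        box shrunk by r plus clearance >= r from each block.
        """
        a = self.half_central_width
        b = self.x_extent
        c = -self.half_cross_width
        if not (-b + r <= x <= b - r and self.y_bottom + r <= y <= self.y_top - r):
            return False
        if y >= c + r:
            return True  # fully inside the cross corridor band
        for x0, x1 in ((a, b), (-b, -a)):
            cx = min(max(x, x0), x1)
            cy = min(max(y, self.y_bottom), c)
            if math.hypot(x - cx, y - cy) < r:
                return False
            if x0 < x < x1 and y < c:  # center inside the solid block
                return False
        return True

    def in_reward_zone(self, x: float, y: float) -> bool:
        if not self.reward_active:
            return False
        return self._in_end_zone(x, y, self.reward_side)

    def in_punishment_zone(self, x: float, y: float) -> bool:
        if not self.reward_active:
            return False
        other = "left" if self.reward_side == "right" else "right"
        return self._in_end_zone(x, y, other)

    def _in_end_zone(self, x: float, y: float, side: str) -> bool:
        if not (-self.half_cross_width <= y <= self.y_top):
            return False
        if side == "right":
            return x >= self.x_extent - self.reward_zone_depth
        return x <= -self.x_extent + self.reward_zone_depth

    def toggled(self) -> "MazeConfig":
        """Same maze with reward (and cue) on the opposite side."""
        other = "left" if self.reward_side == "right" else "right"
        return replace(self, reward_side=other)


class Maze:
    """A :class:`MazeConfig` plus cached wall arrays and the sensor model."""

    def __init__(self, config: MazeConfig):
        self.config = config
        self.seg_a, self.seg_b, self.black_index = config.walls()
        self.vertices = config.wall_vertices()

    # -- sensors -------------------------------------------------------------

    def sense(self, pose: RobotPose) -> SensorFrame:
        return SensorFrame(
            whiskers=self.sense_whiskers(pose),
            camera=self.sense_camera(pose),
            ir=self.sense_ir(pose),
            reward=self.sense_reward(pose),
        )

    def sense_whiskers(self, pose: RobotPose) -> np.ndarray:
        cfg = self.config
        out = np.zeros(N_WHISKERS, dtype=float)
        if not cfg.cue_active:
            return out
        angles = pose.heading + _WHISKER_ANGLES
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        center = np.array([pose.x, pose.y])
        roots = center[None, :] + ROBOT_RADIUS * dirs
        tips = center[None, :] + (ROBOT_RADIUS + WHISKER_LENGTH) * dirs
        hit = segment_disc_intersects(roots, tips, cfg.cue_center(), cfg.cue_radius)
        out[hit] = 1.0
        return out

    def sense_camera(self, pose: RobotPose) -> np.ndarray:
        """20-pixel panorama: pixel = 1 iff some bearing in its 18 deg bin
        sees the black back wall as the first surface.

        Within an angular interval free of wall-vertex bearings the first-hit
        wall cannot change, so casting one ray per sub-interval between
        critical bearings (wall vertices and pixel-bin edges) is exact.
        """
        origin = np.array([pose.x, pose.y])
        rel = self.vertices - origin[None, :]
        vert_bearings = np.arctan2(rel[:, 1], rel[:, 0])
        bin_width = 2.0 * math.pi / N_PIXELS
        bin_edges_rel = -math.pi + bin_width * np.arange(N_PIXELS + 1)
        bin_edges = wrap_angle(pose.heading + bin_edges_rel)
        crit = np.unique(np.concatenate([vert_bearings, bin_edges]))
        # circular midpoints of consecutive critical bearings
        nxt = np.roll(crit, -1)
        gaps = np.mod(nxt - crit, 2.0 * math.pi)
        mids = wrap_angle(crit + gaps / 2.0)
        dirs = np.stack([np.cos(mids), np.sin(mids)], axis=1)
        _, idx = ray_segments_first_hit(origin, dirs, self.seg_a, self.seg_b)
        black = idx == self.black_index
        pixels = np.zeros(N_PIXELS, dtype=float)
        if black.any():
            rel_mids = np.mod(mids - pose.heading + math.pi, 2.0 * math.pi)  # in [0, 2pi)
            bins = np.minimum((rel_mids / bin_width).astype(int), N_PIXELS - 1)
            pixels[np.unique(bins[black])] = 1.0
        return pixels

    def sense_ir(self, pose: RobotPose) -> np.ndarray:
        angles = pose.heading + _IR_ANGLES
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        dist, _ = ray_segments_first_hit(
            np.array([pose.x, pose.y]), dirs, self.seg_a, self.seg_b
        )
        d = np.maximum(dist - ROBOT_RADIUS, 0.0)
        return K_IR * np.maximum(0.0, 1.0 - d / IR_RANGE)

    def sense_reward(self, pose: RobotPose) -> int:
        if self.config.in_reward_zone(pose.x, pose.y):
            return 1
        if self.config.in_punishment_zone(pose.x, pose.y):
            return -1
        return 0

    # -- collision-aware motion ----------------------------------------------

    def resolve_move(self, pose: RobotPose, nx: float, ny: float,
                     nheading: float) -> tuple[RobotPose, bool]:
        """Move toward (nx, ny), sliding along walls; rotation always succeeds.

        Returns the resolved pose and a flag indicating wall contact
        (i.e., any part of the commanded translation had to be cancelled).
        """
        cfg = self.config
        if cfg.contains_disc(nx, ny, ROBOT_RADIUS):
            return RobotPose(nx, ny, nheading), False
        # Cancel the motion component into the wall, axis by axis
        # (all walls are axis-aligned).
        if cfg.contains_disc(nx, pose.y, ROBOT_RADIUS):
            return RobotPose(nx, pose.y, nheading), True
        if cfg.contains_disc(pose.x, ny, ROBOT_RADIUS):
            return RobotPose(pose.x, ny, nheading), True
        return RobotPose(pose.x, pose.y, nheading), True


def step_kinematics(pose: RobotPose, u: float, v_forward: float, c_turn: float,
                    maze: Maze | None = None, dt: float = 1.0
                    ) -> tuple[RobotPose, bool]:
    """Advance the differential-drive robot one environment step.

    Wheel speeds are ``v_left = V - c*(2u-1)`` and ``v_right = V + c*(2u-1)``,
    so ``u > 0.5`` turns the robot left (counter-clockwise). Integration is
    explicit Euler with a fixed axle width. With a maze, collisions are
    resolved by cancelling the motion component into the wall (slide); the
    returned flag reports wall contact.
    """
    if not (math.isfinite(u) and math.isfinite(pose.x) and math.isfinite(pose.y)
            and math.isfinite(pose.heading)):
        raise ValueError("non-finite motor output or pose")
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"motor output u={u} outside [0, 1]")
    if v_forward <= 0 or c_turn <= 0:
        raise ValueError("forward speed and turn constant must be positive")
    m = 2.0 * u - 1.0
    v_left = v_forward - c_turn * m
    v_right = v_forward + c_turn * m
    v = 0.5 * (v_left + v_right)
    omega = (v_right - v_left) / AXLE_WIDTH
    nx = pose.x + v * math.cos(pose.heading) * dt
    ny = pose.y + v * math.sin(pose.heading) * dt
    nheading = wrap_angle(pose.heading + omega * dt).item()
    if maze is None:
        return RobotPose(nx, ny, nheading), False
    return maze.resolve_move(pose, nx, ny, nheading)
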