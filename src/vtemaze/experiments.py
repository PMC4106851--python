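"""Perturbation experiments: start-position robustness, maze-size and
reward-distance sweeps, learning-on/off replays, and group statistics.

The robustness protocol perturbs the starting position of the *whole*
protocol (familiarization is re-run from the perturbed start by default),
runs a fresh session per grid position and maps the success rate. Success
rates are stored as percentages in [0, 100] so that variances across
positions are on the scale on which groups are compared (a variance of a
few hundred separates robust from fragile controllers).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .trial import run_familiarization, run_session, success_rate
from .world import Maze, MazeConfig, RobotPose, ROBOT_RADIUS

__all__ = [
    "GridSpec",
    "RobustnessMap",
    "robustness_grid",
    "maze_size_sweep",
    "reward_distance_sweep",
    "learning_onoff_replay",
    "compare_group_variances",
]


@dataclass(frozen=True)
class GridSpec:
    """Start-position grid inside the central arm.

    Defaults: 7 lateral x 40 longitudinal uniformly spaced positions =
    280 cells, with a margin keeping the robot body off the walls.
    """

    n_lateral: int = 7
    n_longitudinal: int = 40
    margin: float = ROBOT_RADIUS + 0.5

    def positions(self, cfg: MazeConfig) -> list[RobotPose]:
        half = cfg.half_central_width - self.margin
        xs = np.linspace(-half, half, self.n_lateral)
        y_lo = cfg.y_bottom + self.margin
        y_hi = -cfg.half_cross_width - self.margin
        ys = np.linspace(y_lo, y_hi, self.n_longitudinal)
        heading = cfg.start_pose.heading
        poses = [RobotPose(float(x), float(y), heading) for y in ys for x in xs]
        for p in poses:
            if not cfg.contains_disc(p.x, p.y, ROBOT_RADIUS):
                raise ValueError(f"grid position {p} outside the central arm")
        return poses


@dataclass
class RobustnessMap:
    """Success rate (percent) per start position plus aggregates."""

    positions: list[RobotPose]
    rates: np.ndarray          # percent, one per position
    n_trials: int

    @property
    def mean(self) -> float:
        return float(self.rates.mean())

    @property
    def variance(self) -> float:
        return float(self.rates.var(ddof=0))

    def as_matrix(self, grid: GridSpec) -> np.ndarray:
        return self.rates.reshape(grid.n_longitudinal, grid.n_lateral)


def _fresh(controller):
    """Independent copy so each grid cell starts from the same raw controller."""
    return copy.deepcopy(controller)


def robustness_grid(
    controller,
    maze: Maze | MazeConfig,
    grid: GridSpec = GridSpec(),
    *,
    n_trials: int = 100,
    seed: int = 0,
    refamiliarize: bool = True,
) -> RobustnessMap:
    """Success-rate map over start positions in the central arm.

    Each position gets a fresh copy of the controller, a familiarization
    phase from that position (switchable) and a full session.
    """
    cfg = maze.config if isinstance(maze, Maze) else maze
    poses = grid.positions(cfg)
    rates = np.empty(len(poses))
    for k, pose in enumerate(poses):
        c = _fresh(controller)
        if refamiliarize and hasattr(c, "reset_phase"):
            run_familiarization(c, cfg, seed=seed, start_pose=pose)
        records = run_session(c, cfg, n_trials=n_trials, seed=seed,
                              start_pose=pose)
        rates[k] = 100.0 * success_rate(records)
    return RobustnessMap(positions=poses, rates=rates, n_trials=n_trials)


def maze_size_sweep(
    controller,
    maze: Maze | MazeConfig,
    scales: Sequence[tuple[float, float]],
    grid: GridSpec = GridSpec(),
    *,
    n_trials: int = 100,
    seed: int = 0,
) -> dict[tuple[float, float], RobustnessMap]:
    """Robustness grid repeated for scaled maze widths/heights.

    ``scales`` are (width_scale, height_scale) factors applied to all arm
    widths and lengths respectively; (1, 1) reproduces the baseline grid
    bit for bit. Sizes below the robot diameter raise a config error.
    """
    cfg = maze.config if isinstance(maze, Maze) else maze
    out = {}
    for (wx, wy) in scales:
        scaled = replace(
            cfg,
            central_arm_width=cfg.central_arm_width * wx,
            cross_arm_length=cfg.cross_arm_length * wx,
            central_arm_length=cfg.central_arm_length * wy,
            cross_arm_width=cfg.cross_arm_width * wy,
            start_pose=None,
        )
        out[(wx, wy)] = robustness_grid(controller, scaled, grid,
                                        n_trials=n_trials, seed=seed)
    return out


def reward_distance_sweep(
    controller,
    maze: Maze | MazeConfig,
    distances: Sequence[float],
    *,
    n_trials: int = 100,
    seed: int = 0,
    refamiliarize: bool = True,
) -> dict[float, float]:
    """Success rate (percent) with the reward moved deeper into its arm.

    ``distances`` are cross-arm lengths (cm from the junction edge to the
    arm end); each must be at least the original length and the reward
    zone stays the distal slab of the (now longer) arm.
    """
    cfg = maze.config if isinstance(maze, Maze) else maze
    out = {}
    for d in distances:
        if d < cfg.cross_arm_length:
            raise ValueError("reward distance below the original arm length")
        stretched = replace(cfg, cross_arm_length=float(d))
        c = _fresh(controller)
        if refamiliarize and hasattr(c, "reset_phase"):
            run_familiarization(c, stretched, seed=seed)
        records = run_session(c, stretched, n_trials=n_trials, seed=seed)
        out[float(d)] = 100.0 * success_rate(records)
    return out


def learning_onoff_replay(
    controller,
    maze: Maze | MazeConfig,
    weight_snapshots: Sequence[Mapping],
    *,
    n_trials: int = 100,
    seed: int = 0,
    start_pose=None,
    evaluate: Callable | None = None,
) -> dict[str, np.ndarray]:
    """Paired success curves: per-trial weight snapshots replayed with
    learning frozen vs learning active.

    For each snapshot t, the controller is re-initialized with the weights
    the baseline run had at the start of trial t, then evaluated over a
    session twice. ``evaluate(controller, learning)`` may override the
    default single-session percent-success evaluation (e.g. to perturb
    start positions).
    """
    cfg = maze.config if isinstance(maze, Maze) else maze

    def default_eval(c, learning: bool) -> float:
        records = run_session(c, cfg, n_trials=n_trials, seed=seed,
                              learning=learning, reset_phase=False,
                              start_pose=start_pose)
        return 100.0 * success_rate(records)

    ev = evaluate if evaluate is not None else default_eval
    frozen = np.empty(len(weight_snapshots))
    active = np.empty(len(weight_snapshots))
    for t, snap in enumerate(weight_snapshots):
        for learning, dest in ((False, frozen), (True, active)):
            c = _fresh(controller)
            c.reset_phase()
            c.set_weights(snap)
            dest[t] = ev(c, learning)
    return {"frozen": frozen, "learning": active}


def compare_group_variances(
    groups: Mapping[str, Sequence[float]],
    focal: str = "HL",
    *,
    method: str = "t",
    n_permutations: int = 10000,
    seed: int = 0,
) -> dict:
    """Two-sample test of per-robot success-rate variances, focal vs pooled rest.

    ``groups`` maps group label to the per-robot variance values. Returns
    the statistic and p-value of a two-sample t-test (default) or a
    permutation test on the difference of means.
    """
    if focal not in groups:
        raise ValueError(f"focal group {focal!r} missing")
    a = np.asarray(groups[focal], dtype=float)
    b = np.concatenate([np.asarray(v, dtype=float)
                        for k, v in groups.items() if k != focal])
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two robots per group")
    if method == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return {"method": "welch_t", "statistic": float(res.statistic),
                "p_value": float(res.pvalue), "n_focal": a.size, "n_rest": b.size}
    if method == "permutation":
        rng = np.random.default_rng(seed)
        observed = a.mean() - b.mean()
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[: a.size].mean() - pooled[a.size:].mean()) >= abs(observed):
                count += 1
        return {"method": "permutation", "statistic": float(observed),
                "p_value": (count + 1) / (n_permutations + 1),
                "n_focal": a.size, "n_rest": b.size}
    raise ValueError(f"unknown method {method!r}")
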