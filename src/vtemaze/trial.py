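"""Trial protocols: single trials, the familiarization phase, and sessions.

A *trial* steps the environment at 1-step cadence (pose, reward channel,
wheel speeds) while the controller is ticked every ``delta`` environment
steps; it ends on first entry into the reward or punishment zone or at the
step budget. The *familiarization phase* precedes maze solving: cue and
reward are deactivated, the motor command is clamped to one of two fixed
values alternating on each wall contact, and each wall contact resets the
robot to its start pose (20 episodes). A *session* is 100 maze-solving
trials in which the rewarded side (and the tactile cue with it) switches
after every 5th trial and weights persist across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .controller import MODULES
from .world import Maze, MazeConfig, RobotPose, step_kinematics

__all__ = [
    "NeuralLog",
    "TrialRecord",
    "run_trial",
    "run_familiarization",
    "run_session",
    "success_rate",
    "FAMILIARIZATION_EPISODES",
    "FAMILIARIZATION_CLAMPS",
    "REWARD_SWITCH_PERIOD",
]

FAMILIARIZATION_EPISODES = 20
#: Clamped motor outputs: 0.8 induces a left turn, 0.2 a right turn.
FAMILIARIZATION_CLAMPS = (0.8, 0.2)
REWARD_SWITCH_PERIOD = 5  # trials between reward-side switches

Outcome = Literal["reward", "punishment", "timeout", "wall_reset"]


@dataclass
class NeuralLog:
    """Per-neural-step module activities of one trial."""

    s: dict[str, np.ndarray]   # module -> (n_ticks, size) state units
    v: dict[str, np.ndarray]   # module -> (n_ticks, size) virtual units
    u: np.ndarray              # (n_ticks,) effective motor output

    def __len__(self) -> int:
        return len(self.u)


@dataclass
class TrialRecord:
    """Outcome and full logs of one trial."""

    trial_index: int
    phase: Literal["familiarization", "maze_solving"]
    outcome: Outcome
    env_steps: int
    trajectory: np.ndarray                  # (env_steps + 1, 3): x, y, heading
    neural_log: NeuralLog | None = None
    weight_snapshots: dict | None = None    # per-pair mean |W| per neural step
    reward_side: str | None = None
    seed: int | None = None

    @property
    def success(self) -> bool:
        return self.outcome == "reward"

    def summary(self) -> dict:
        return {
            "trial_index": self.trial_index,
            "phase": self.phase,
            "outcome": self.outcome,
            "env_steps": self.env_steps,
            "n_neural_steps": 0 if self.neural_log is None else len(self.neural_log),
            "reward_side": self.reward_side,
            "seed": self.seed,
        }


def _snapshot_mean_weights(controller) -> dict[tuple[str, str], float]:
    return {p: float(np.abs(w).mean()) for p, w in controller.W.items()}


def run_trial(
    controller,
    maze: Maze | MazeConfig,
    *,
    phase: str = "maze_solving",
    learning: bool = True,
    seed: int = 0,
    trial_index: int = 0,
    start_pose: RobotPose | None = None,
    clamp_motor: float | None = None,
    motor_filter: Callable[[float], float] | None = None,
    record_weights: bool = False,
) -> TrialRecord:
    """Run one trial until reward, punishment, timeout or (familiarization
    only) wall contact.

    The simulation is fully deterministic: identical controller state,
    maze and arguments reproduce the record bit for bit; ``seed`` is
    recorded for provenance and forwarded to stochastic controllers.
    """
    if isinstance(maze, MazeConfig):
        maze = Maze(maze)
    cfg = maze.config
    params = controller.params
    delta = int(params.delta)
    v_forward = params.v_forward
    c_turn = controller.motor_constant(phase)
    controller.learning = learning

    pose = start_pose if start_pose is not None else cfg.start_pose
    if not cfg.contains_disc(pose.x, pose.y, 0.0):
        raise ValueError("start pose outside maze free space")
    if hasattr(controller, "begin_trial"):
        controller.begin_trial(maze)

    traj = [(pose.x, pose.y, pose.heading)]
    log_s = {m: [] for m in MODULES}
    log_v = {m: [] for m in MODULES}
    log_u: list[float] = []
    w_snaps: dict[tuple[str, str], list[float]] | None = None
    if record_weights and hasattr(controller, "W"):
        w_snaps = {p: [] for p in controller.W}

    u = clamp_motor if clamp_motor is not None else controller.u
    outcome: str | None = None
    t = 0
    while t < cfg.timeout_steps:
        if t % delta == 0:
            if clamp_motor is not None:
                controller.u = clamp_motor
            controller.observe_pose(pose)
            frame = maze.sense(pose) if controller.needs_sensors else None
            u = controller.tick(frame)
            if clamp_motor is not None:
                u = clamp_motor
                controller.u = clamp_motor
            elif motor_filter is not None:
                u_eff = motor_filter(u)
                if u_eff != u:
                    u = u_eff
                    controller.u = u_eff  # learning sees the overridden state
            if hasattr(controller, "s"):
                for m in MODULES:
                    log_s[m].append(controller.s[m].copy())
                    log_v[m].append(controller.v[m].copy())
            log_u.append(u)
            if w_snaps is not None:
                for p, val in _snapshot_mean_weights(controller).items():
                    w_snaps[p].append(val)
        pose, contact = step_kinematics(pose, u, v_forward, c_turn, maze)
        t += 1
        traj.append((pose.x, pose.y, pose.heading))
        if phase == "familiarization":
            if contact:
                outcome = "wall_reset"
                break
        else:
            if cfg.in_reward_zone(pose.x, pose.y):
                outcome = "reward"
                break
            if cfg.in_punishment_zone(pose.x, pose.y):
                outcome = "punishment"
                break
    if outcome is None:
        outcome = "timeout"

    neural_log = None
    if log_u and log_s["motor"]:
        neural_log = NeuralLog(
            s={m: np.array(log_s[m]) for m in MODULES},
            v={m: np.array(log_v[m]) for m in MODULES},
            u=np.array(log_u),
        )
    elif log_u:
        neural_log = NeuralLog(s={}, v={}, u=np.array(log_u))
    return TrialRecord(
        trial_index=trial_index,
        phase=phase,  # type: ignore[arg-type]
        outcome=outcome,  # type: ignore[arg-type]
        env_steps=t,
        trajectory=np.array(traj),
        neural_log=neural_log,
        weight_snapshots=(None if w_snaps is None
                          else {p: np.array(v) for p, v in w_snaps.items()}),
        reward_side=cfg.reward_side if cfg.reward_active else None,
        seed=seed,
    )


def run_familiarization(
    controller,
    maze: Maze | MazeConfig,
    *,
    n_episodes: int = FAMILIARIZATION_EPISODES,
    clamps: tuple[float, float] = FAMILIARIZATION_CLAMPS,
    seed: int = 0,
    start_pose: RobotPose | None = None,
) -> list[TrialRecord]:
    """Familiarization phase: cue/reward off, clamped alternating motor.

    Hebbian learning stays active throughout; weights (and virtual units)
    carry over into the maze-solving phase. The phase reset (weights and
    virtual units to zero) happens once, at the start.
    """
    cfg = maze.config if isinstance(maze, Maze) else maze
    from dataclasses import replace
    fam_maze = Maze(replace(cfg, cue_active=False, reward_active=False))
    if hasattr(controller, "reset_phase"):
        controller.reset_phase()
    records = []
    for k in range(n_episodes):
        rec = run_trial(
            controller, fam_maze,
            phase="familiarization", learning=True, seed=seed, trial_index=k,
            start_pose=start_pose, clamp_motor=clamps[k % 2],
        )
        records.append(rec)
    return records


def run_session(
    controller,
    maze: Maze | MazeConfig,
    *,
    n_trials: int = 100,
    learning: bool = True,
    seed: int = 0,
    start_pose: RobotPose | None = None,
    motor_filter: Callable[[float], float] | None = None,
    reset_phase: bool = True,
    snapshot_initial_weights: bool = False,
    record_weights: bool = False,
    on_trial_start: Callable[[int], None] | None = None,
) -> list[TrialRecord] | tuple[list[TrialRecord], list[dict]]:
    """Maze-solving session: the rewarded side switches every 5 trials.

    With ``snapshot_initial_weights`` the full weight set at the start of
    each trial is also returned (used by the learning-on/off replay
    experiment).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = maze.config if isinstance(maze, Maze) else maze
    if reset_phase and hasattr(controller, "reset_phase"):
        controller.reset_phase()
    base = Maze(cfg)
    toggled = Maze(cfg.toggled())
    records = []
    snapshots = []
    for k in range(n_trials):
        m = base if (k // REWARD_SWITCH_PERIOD) % 2 == 0 else toggled
        if on_trial_start is not None:
            on_trial_start(k)
        if snapshot_initial_weights and hasattr(controller, "copy_weights"):
            snapshots.append(controller.copy_weights())
        rec = run_trial(
            controller, m,
            phase="maze_solving", learning=learning, seed=seed, trial_index=k,
            start_pose=start_pose, motor_filter=motor_filter,
            record_weights=record_weights,
        )
        records.append(rec)
    if snapshot_initial_weights:
        return records, snapshots
    return records


def success_rate(records: Sequence[TrialRecord]) -> float:
    """Fraction of trials that reached the reward, in [0, 1]."""
    if not records:
        return 0.0
    return sum(r.success for r in records) / len(records)
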