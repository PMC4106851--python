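"""Genetic algorithm over the 49 controller parameters.

Real-valued genomes in [0, 1]^49 decode through fixed affine range maps to
:class:`~vtemaze.controller.ControllerParams`. Evolution follows a plain
generational GA: tournament selection, single-point crossover (p = 0.7),
per-gene uniform-redraw mutation (p = 0.01) and elitism (the five best
individuals copied unchanged). Fitness is the summed per-trial reward of a
100-trial maze-solving protocol from one fixed start position, preceded by
familiarization; with the default table (reward = +5, punishment = timeout
= 0) a perfect run scores 500.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .controller import ALL_PAIRS, ControllerParams, HebbianController
from .trial import run_familiarization, run_session
from .world import Maze, MazeConfig

__all__ = [
    "GENOME_LENGTH",
    "GENE_RANGES",
    "DEFAULT_REWARD_TABLE",
    "GAConfig",
    "GAState",
    "decode_genome",
    "random_genome",
    "evaluate_fitness",
    "evolve",
]

GENOME_LENGTH = 49

#: Affine range of each non-rate gene, in decode order after the 40 rates.
GENE_RANGES: dict[str, tuple[float, float]] = {
    "delta": (10.0, 30.0),   # neural update period, env steps (rounded)
    "tau": (1.0, 5.0),       # delayed-state lag, neural steps (rounded)
    "slope": (0.1, 10.0),    # sigmoid slope a
    "c_familiarization": (0.1, 5.0),
    "c_maze": (0.1, 5.0),
    "v_forward": (0.1, 5.0),
    "k_light": (0.1, 5.0),
    "k_touch": (0.1, 5.0),
    "k_reward": (0.1, 5.0),
}
_SCALAR_ORDER = tuple(GENE_RANGES)

DEFAULT_REWARD_TABLE: Mapping[str, float] = {
    "reward": 5.0, "punishment": 0.0, "timeout": 0.0,
}


def decode_genome(genes: Sequence[float]) -> ControllerParams:
    """Map a [0, 1]^49 genome to controller parameters.

    Layout: genes 0-19 are learning rates, 20-39 forgetting rates (both in
    [0, 1], one per directed pair in :data:`~vtemaze.controller.ALL_PAIRS`
    order), then the nine scalars in :data:`GENE_RANGES` order. Genes are
    clamped to [0, 1] before mapping; delta and tau round to integers.
    """
    g = np.clip(np.asarray(genes, dtype=float), 0.0, 1.0)
    if g.shape != (GENOME_LENGTH,):
        raise ValueError(f"genome must have length {GENOME_LENGTH}, got {g.shape}")
    eta = {p: float(g[k]) for k, p in enumerate(ALL_PAIRS)}
    zeta = {p: float(g[20 + k]) for k, p in enumerate(ALL_PAIRS)}
    scalars = {}
    for k, name in enumerate(_SCALAR_ORDER):
        lo, hi = GENE_RANGES[name]
        scalars[name] = lo + g[40 + k] * (hi - lo)
    scalars["delta"] = int(round(scalars["delta"]))
    scalars["tau"] = int(round(scalars["tau"]))
    return ControllerParams(eta=eta, zeta=zeta, **scalars)


def random_genome(rng: np.random.Generator) -> np.ndarray:
    return rng.random(GENOME_LENGTH)


def evaluate_fitness(
    individual,
    maze: Maze | MazeConfig,
    n_trials: int = 100,
    *,
    reward_table: Mapping[str, float] = DEFAULT_REWARD_TABLE,
    topology: str = "full",
    familiarize: bool = True,
    seed: int = 0,
) -> float:
    """Fitness of a genome or controller over the standard evaluation protocol.

    Runs familiarization (20 clamped episodes) then ``n_trials`` maze-solving
    trials from the fixed start pose, and sums the per-outcome rewards.
    """
    if isinstance(individual, HebbianController) or hasattr(individual, "tick"):
        controller = individual
    else:
        controller = HebbianController(decode_genome(individual), topology=topology)
    cfg = maze.config if isinstance(maze, Maze) else maze
    if familiarize:
        run_familiarization(controller, cfg, seed=seed)
    records = run_session(controller, cfg, n_trials=n_trials, seed=seed,
                          reset_phase=True)
    return float(sum(reward_table.get(r.outcome, 0.0) for r in records))


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 1000
    elite: int = 5
    tournament_size: int = 3
    crossover_prob: float = 0.7
    mutation_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.population_size <= self.elite:
            raise ValueError("population must exceed the elite count")


@dataclass
class GAState:
    """Evolution history and final population."""

    population: np.ndarray          # (N, 49), final generation
    fitness: np.ndarray             # (N,), final generation
    generation: int
    best_history: np.ndarray        # (generations,), best fitness per generation
    mean_history: np.ndarray
    best_genome: np.ndarray
    best_fitness: float
    seed: int
    quantile_history: np.ndarray | None = None  # (generations, 3): q25, q50, q75

    def history_frame(self):
        import pandas as pd
        frame = pd.DataFrame({
            "generation": np.arange(len(self.best_history)),
            "best": self.best_history,
            "mean": self.mean_history,
        })
        if self.quantile_history is not None:
            frame["q25"] = self.quantile_history[:, 0]
            frame["median"] = self.quantile_history[:, 1]
            frame["q75"] = self.quantile_history[:, 2]
        return frame


def _tournament(rng: np.random.Generator, fitness: np.ndarray, k: int) -> int:
    contenders = rng.integers(0, len(fitness), size=k)
    return int(contenders[np.argmax(fitness[contenders])])


def evolve(
    fitness_fn: Callable[[np.ndarray], float],
    config: GAConfig = GAConfig(),
    *,
    initial_population: np.ndarray | None = None,
    callback: Callable[[int, "GAState"], None] | None = None,
) -> GAState:
    """Run the generational GA; fully reproducible under a fixed seed.

    ``fitness_fn`` maps a genome array to a scalar (higher is better); with
    a deterministic fitness the per-generation best is non-decreasing by
    the elite-copy guarantee.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.population_size, GENOME_LENGTH
    if initial_population is not None:
        pop = np.array(initial_population, dtype=float)
        if pop.shape != (n, L):
            raise ValueError("initial population has wrong shape")
    else:
        pop = rng.random((n, L))
    best_hist, mean_hist, quant_hist = [], [], []
    fitness = np.empty(n)
    for gen in range(config.generations):
        for i in range(n):
            fitness[i] = fitness_fn(pop[i])
        order = np.argsort(fitness)[::-1]
        best_hist.append(float(fitness[order[0]]))
        mean_hist.append(float(fitness.mean()))
        quant_hist.append(np.quantile(fitness, [0.25, 0.5, 0.75]))
        if callback is not None:
            snap = GAState(pop.copy(), fitness.copy(), gen,
                           np.array(best_hist), np.array(mean_hist),
                           pop[order[0]].copy(), best_hist[-1], config.seed,
                           np.array(quant_hist))
            callback(gen, snap)
        if gen == config.generations - 1:
            break
        new_pop = [pop[i].copy() for i in order[: config.elite]]
        while len(new_pop) < n:
            pa = pop[_tournament(rng, fitness, config.tournament_size)]
            pb = pop[_tournament(rng, fitness, config.tournament_size)]
            child_a, child_b = pa.copy(), pb.copy()
            if rng.random() < config.crossover_prob:
                cut = int(rng.integers(1, L))
                child_a = np.concatenate([pa[:cut], pb[cut:]])
                child_b = np.concatenate([pb[:cut], pa[cut:]])
            for child in (child_a, child_b):
                mask = rng.random(L) < config.mutation_rate
                if mask.any():
                    child[mask] = rng.random(int(mask.sum()))
                if len(new_pop) < n:
                    new_pop.append(child)
        pop = np.array(new_pop)
    order = np.argsort(fitness)[::-1]
    return GAState(
        population=pop, fitness=fitness.copy(), generation=config.generations - 1,
        best_history=np.array(best_hist), mean_history=np.array(mean_hist),
        best_genome=pop[order[0]].copy(), best_fitness=float(fitness[order[0]]),
        seed=config.seed, quantile_history=np.array(quant_hist),
    )
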