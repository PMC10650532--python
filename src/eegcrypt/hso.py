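"""Hybridized Spoofing Optimization (HSO): a crow/sparrow hybrid swarm.

HSO blends two swarm-intelligence update rules over a population of agents
in a box (by default the unit hypercube, matching fusion weights in [0,1]):

* the **corvid** (crow-search) move — agent e follows the memorized best
  position Z_f of a randomly chosen flock mate:

      J(n+1) = J(n) + lambda1 * a * (Z_f - J(n)),   lambda1 ~ U(0, 1)

  with flight length ``a``; with probability 1 - Paw (the mate is "aware")
  the agent instead relocates uniformly at random in the box;

* the **gregarious** (sparrow-search) move — agents worse than the global
  best are drawn toward a velocity-augmented best position,

      J(n+1) = J'best + theta * (J(n) - J'best),
      J'best = Jbest * (1 + v1 * omega) + V(n)

  while an agent already at the global best is pushed away from the global
  worst, J(n+1) = J(n) + chi * |J(n) - Jworst| / (j_e - j_ws + eps). The
  velocity V follows an exponentially decayed random walk
  V(n+1) = omega * V(n) + v1 * U(-1, 1)^d, V(0) = 0.

Each iteration every agent takes the corvid move with probability 0.5 and
the gregarious move otherwise. Candidate positions are clipped to the box;
an agent's memory is replaced only on strict fitness improvement, so the
best-fitness trace is monotonically non-increasing. Minimization is the
convention throughout; classification objectives are wrapped as
1 - accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cnn import FusionParams, ensemble_fuse

__all__ = [
    "HSOConfig",
    "SearchAgent",
    "Swarm",
    "HSOResult",
    "init_population",
    "corvid_update",
    "gregarious_update",
    "greedy_memory_update",
    "optimize",
    "tune_fusion",
]

_EPS = 1e-12


@dataclass(frozen=True)
class HSOConfig:
    """HSO hyperparameters.

    ``m`` population size; ``max_iterations`` I_max; ``flight_length`` the
    corvid step scale a; ``awareness_prob`` Paw (escape jumps happen with
    probability 1 - Paw); ``theta_range`` / ``chi_range`` the draw ranges of
    the gregarious step scalars; ``v1`` / ``omega`` the velocity gain and
    inertia; ``seed`` the RNG seed.
    """

    m: int = 20
    max_iterations: int = 100
    flight_length: float = 2.0
    awareness_prob: float = 0.85
    theta_range: tuple[float, float] = (0.0, 1.0)
    chi_range: tuple[float, float] = (-1.0, 1.0)
    v1: float = 0.05
    omega: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("population size m must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.awareness_prob <= 1.0:
            raise ValueError("awareness_prob must lie in [0, 1]")
        if self.flight_length <= 0:
            raise ValueError("flight_length must be positive")


@dataclass
class SearchAgent:
    """One swarm member: current position and its memorized best."""

    position: np.ndarray
    memory: np.ndarray
    fitness: float
    memory_fitness: float


@dataclass
class Swarm:
    """Population state at one iteration."""

    agents: list[SearchAgent]
    global_best_position: np.ndarray
    global_best_fitness: float
    global_worst_position: np.ndarray
    global_worst_fitness: float
    velocity: np.ndarray
    iteration: int = 0

    def refresh_extremes(self) -> None:
        fits = [a.memory_fitness for a in self.agents]
        b, w = int(np.argmin(fits)), int(np.argmax(fits))
        self.global_best_position = self.agents[b].memory.copy()
        self.global_best_fitness = self.agents[b].memory_fitness
        self.global_worst_position = self.agents[w].memory.copy()
        self.global_worst_fitness = self.agents[w].memory_fitness


@dataclass
class HSOResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # per-iteration global best fitness (non-increasing)
    n_evaluations: int


def _box(bounds: tuple[float, float] | Sequence[tuple[float, float]], d: int):
    arr = np.asarray(bounds, dtype=np.float64)
    if arr.shape == (2,):
        lo = np.full(d, arr[0])
        hi = np.full(d, arr[1])
    elif arr.shape == (d, 2):
        lo, hi = arr[:, 0], arr[:, 1]
    else:
        raise ValueError("bounds must be (lo, hi) or a (d, 2) array")
    if np.any(hi <= lo):
        raise ValueError("upper bounds must exceed lower bounds")
    return lo, hi


def init_population(
    objective: Callable[[np.ndarray], float],
    d: int,
    config: HSOConfig,
    bounds: tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
    seed_positions: Sequence[np.ndarray] | None = None,
) -> Swarm:
    """Uniform random population in the box; memory = initial position.

    ``seed_positions`` optionally replaces the first agents' positions with
    known candidate solutions (used by fusion tuning to seed one-hot weight
    vectors).
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = _box(bounds, d)
    positions = rng.uniform(lo, hi, (config.m, d))
    if seed_positions:
        for i, p in enumerate(seed_positions[: config.m]):
            positions[i] = np.clip(np.asarray(p, dtype=np.float64), lo, hi)
    agents = []
    for p in positions:
        f = float(objective(p))
        agents.append(SearchAgent(p.copy(), p.copy(), f, f))
    swarm = Swarm(
        agents=agents,
        global_best_position=np.empty(d),
        global_best_fitness=np.inf,
        global_worst_position=np.empty(d),
        global_worst_fitness=-np.inf,
        velocity=np.zeros(d),
    )
    swarm.refresh_extremes()
    return swarm


def corvid_update(
    agent: SearchAgent,
    mate_memory: np.ndarray,
    config: HSOConfig,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
    lam: float | None = None,
) -> np.ndarray:
    """Crow-search move toward a flock mate's memorized cache.

    ``lam`` forces the U(0,1) draw (for testing); by default it is drawn
    fresh. With probability 1 - Paw the agent jumps uniformly in the box.
    """
    d = agent.position.size
    lo, hi = _box(bounds, d)
    if rng.uniform() >= config.awareness_prob:
        return rng.uniform(lo, hi, d)
    lam = rng.uniform() if lam is None else lam
    cand = agent.position + lam * config.flight_length * (mate_memory - agent.position)
    return np.clip(cand, lo, hi)


def gregarious_update(
    agent: SearchAgent,
    swarm: Swarm,
    config: HSOConfig,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
    theta: float | None = None,
    chi: float | None = None,
) -> np.ndarray:
    """Sparrow-style best-anchored move (or worst-repulsion at the best)."""
    d = agent.position.size
    lo, hi = _box(bounds, d)
    if theta is None:
        theta = rng.uniform(*config.theta_range)
    if chi is None:
        chi = rng.uniform(*config.chi_range)
    if agent.fitness > swarm.global_best_fitness:
        best_aug = swarm.global_best_position * (1.0 + config.v1 * config.omega) + swarm.velocity
        cand = best_aug + theta * (agent.position - best_aug)
    else:
        gap = agent.fitness - swarm.global_worst_fitness
        cand = agent.position + chi * np.abs(
            agent.position - swarm.global_worst_position
        ) / (gap + _EPS)
    return np.clip(cand, lo, hi)


def greedy_memory_update(
    agent: SearchAgent,
    candidate: np.ndarray,
    objective: Callable[[np.ndarray], float],
) -> SearchAgent:
    """Move to the candidate and refresh memory on strict improvement only."""
    f = float(objective(candidate))
    agent.position = np.asarray(candidate, dtype=np.float64).copy()
    agent.fitness = f
    if f < agent.memory_fitness:
        agent.memory = agent.position.copy()
        agent.memory_fitness = f
    return agent


def optimize(
    objective: Callable[[np.ndarray], float],
    d: int,
    config: HSOConfig | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
    seed_positions: Sequence[np.ndarray] | None = None,
) -> HSOResult:
    """Run HSO on ``objective`` over the box; returns the global best.

    The returned trace holds the global best fitness after each iteration
    and is non-increasing by construction (greedy memory rule).
    """
    config = config or HSOConfig()
    rng = np.random.default_rng(config.seed)
    swarm = init_population(objective, d, config, bounds, rng, seed_positions)
    n_evals = config.m
    trace = np.empty(config.max_iterations)
    for it in range(config.max_iterations):
        swarm.velocity = config.omega * swarm.velocity + config.v1 * rng.uniform(-1, 1, d)
        for agent in swarm.agents:
            if rng.uniform() < 0.5:
                mate = swarm.agents[rng.integers(len(swarm.agents))]
                cand = corvid_update(agent, mate.memory, config, rng, bounds)
            else:
                cand = gregarious_update(agent, swarm, config, rng, bounds)
            greedy_memory_update(agent, cand, objective)
            n_evals += 1
        swarm.refresh_extremes()
        swarm.iteration = it + 1
        trace[it] = swarm.global_best_fitness
    return HSOResult(
        best_position=swarm.global_best_position,
        best_fitness=float(swarm.global_best_fitness),
        trace=trace,
        n_evaluations=n_evals,
    )


def tune_fusion(
    member_probs: Sequence[np.ndarray],
    val_labels: np.ndarray,
    config: HSOConfig | None = None,
    n_feature_dims: int = 0,
) -> FusionParams:
    """Tune ensemble fusion weights (and optionally a feature mask) by HSO.

    ``member_probs`` holds each member's class-probability matrix on a
    validation set; the objective is 1 - fused validation accuracy. The
    first ``len(member_probs)`` search dimensions decode to member weights;
    any further dimensions are thresholded at 0.5 into a binary feature
    mask. The initial population is seeded with the one-hot weight vectors,
    so the tuned fusion is never worse on the validation set than the best
    single member.
    """
    k = len(member_probs)
    if k < 1:
        raise ValueError("at least one ensemble member required")
    probs = [np.asarray(p, dtype=np.float64) for p in member_probs]
    y = np.asarray(val_labels, dtype=np.intp)
    if y.size == 0:
        raise ValueError("validation set is empty")
    for p in probs:
        if p.shape[0] != y.size:
            raise ValueError("member probabilities and labels length mismatch")
    config = config or HSOConfig(m=12, max_iterations=40)
    d = k + n_feature_dims

    def objective(x: np.ndarray) -> float:
        w = x[:k]
        if w.sum() <= 0:
            return 1.0 + 1e-6  # invalid decode: worse than any accuracy
        fused = sum(wi * p for wi, p in zip(w, probs)) / w.sum()
        acc = float(np.mean(fused.argmax(axis=1) == y))
        return 1.0 - acc

    one_hots = [np.concatenate([np.eye(k)[i], np.full(n_feature_dims, 0.75)]) for i in range(k)]
    result = optimize(objective, d, config, bounds=(0.0, 1.0), seed_positions=one_hots)
    w = result.best_position[:k]
    mask = None
    if n_feature_dims:
        mask = result.best_position[k:] >= 0.5
        if not mask.any():
            mask[np.argmax(result.best_position[k:])] = True
    return FusionParams(weights=w, selected_features=mask)
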