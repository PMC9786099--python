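"""Canonical continuous grey wolf optimizer.

The pack's three best agents (alpha, beta, delta) steer every other agent.
Each update draws stochastic coefficient vectors ``A`` and ``C`` per leader,
forms the encircling displacement ``D_k = |C_k * X_k - X|``, moves toward
each leader via ``X_k' = X_k - A_k * D_k`` and averages the three
candidates. The scale ``a`` of ``A`` decays linearly from 2 to 0 over the
iteration budget, shifting the pack from exploration to exploitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from igwo.config import OptimizerConfig
from igwo.sharing import niche_counts, rank_agents, select_leaders

logger = logging.getLogger(__name__)


@dataclass
class SearchAgent:
    """One wolf: a continuous position plus its fitness bookkeeping."""

    position: np.ndarray
    fitness: float = np.nan
    shared_fitness: float | None = None
    flags: np.ndarray | None = None


@dataclass
class CoefficientState:
    """Snapshot of the stochastic coefficients at one update."""

    t: int
    T: int
    a: float
    A: np.ndarray
    C: np.ndarray
    r1: np.ndarray
    r2: np.ndarray


@dataclass
class LeaderTriplet:
    """The three best positions guiding an update, best first."""

    alpha_position: np.ndarray
    beta_position: np.ndarray
    delta_position: np.ndarray
    alpha_fitness: float
    beta_fitness: float
    delta_fitness: float

    @property
    def positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.alpha_position, self.beta_position, self.delta_position)


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    evaluations: int
    leaders: LeaderTriplet | None = field(default=None)


def coefficient_schedule(t: float, T: int) -> float:
    """Linear decay of the coefficient scale: ``a = 2 - 2 t / T``.

    Accepts fractional ``t`` so the midpoint is well-defined for odd
    budgets. ``a`` runs from 2 at t=0 down to 0 at t=T.
    """
    if T < 1:
        raise ValueError(f"iteration budget T must be >= 1, got {T}")
    if not 0 <= t <= T:
        raise ValueError(f"iteration index t must lie in [0, {T}], got {t}")
    return 2.0 - 2.0 * t / T


def draw_coefficients(
    a: float, dimensionality: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (A, C) coefficient pair: ``A = 2 a r1 - a``, ``C = 2 r2``.

    ``r1`` and ``r2`` are fresh Uniform[0,1) vectors, so each component of
    ``A`` lies in [-a, a) and each component of ``C`` in [0, 2).
    """
    if not 0.0 <= a <= 2.0:
        raise ValueError(f"coefficient scale a must lie in [0, 2], got {a}")
    r1 = rng.random(dimensionality)
    r2 = rng.random(dimensionality)
    return 2.0 * a * r1 - a, 2.0 * r2


def leader_guided_update(
    position: np.ndarray,
    leaders: LeaderTriplet,
    a: float | None = None,
    rng: np.random.Generator | None = None,
    domain_low: float = 0.0,
    domain_high: float = 1.0,
    coefficients: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Move one agent toward the averaged alpha/beta/delta candidates.

    For each leader k: ``D_k = |C_k * X_k - X|`` and
    ``X_k' = X_k - A_k * D_k``; the new position is the componentwise mean
    of the three candidates, clamped to the domain box. Coefficients are
    drawn independently per leader unless ``coefficients`` pins them
    (used by tests to cross-check against a straight-line transcription).
    """
    position = np.asarray(position, dtype=float)
    dim = position.shape[0]
    for leader_pos in leaders.positions:
        if np.asarray(leader_pos).shape[0] != dim:
            raise ValueError("leader and agent positions must share dimensionality")
    if coefficients is None:
        if a is None or rng is None:
            raise ValueError("either coefficients or (a, rng) must be supplied")
        coefficients = [draw_coefficients(a, dim, rng) for _ in range(3)]
    candidates = np.empty((3, dim))
    for k, (leader_pos, (A, C)) in enumerate(zip(leaders.positions, coefficients)):
        leader_pos = np.asarray(leader_pos, dtype=float)
        D = np.abs(C * leader_pos - position)
        candidates[k] = leader_pos - A * D
    return np.clip(candidates.mean(axis=0), domain_low, domain_high)


def _initial_positions(config: OptimizerConfig, rng: np.random.Generator) -> np.ndarray:
    span = config.domain_high - config.domain_low
    return config.domain_low + span * rng.random(
        (config.population_size, config.dimensionality)
    )


def run_gwo(
    objective,
    config: OptimizerConfig,
    initial_positions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> OptimizationResult:
    """Run the full optimizer loop over a user-supplied objective.

    Evaluates all agents, ranks alpha/beta/delta, then for each iteration
    updates every agent (leaders included) via :func:`leader_guided_update`
    with the scheduled ``a``, re-evaluates and re-ranks. When
    ``config.sharing_radius`` is enabled, leader ranking uses shared
    fitness (niche-penalized) while best-so-far tracking always uses raw
    fitness. Identical seeds yield identical results.
    """
    if config.population_size < 3:
        raise ValueError("population_size must be >= 3 to rank three leaders")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if initial_positions is None:
        positions = _initial_positions(config, rng)
    else:
        positions = np.array(initial_positions, dtype=float)
        if positions.shape != (config.population_size, config.dimensionality):
            raise ValueError(
                f"initial_positions shape {positions.shape} != "
                f"({config.population_size}, {config.dimensionality})")
        positions = np.clip(positions, config.domain_low, config.domain_high)

    maximize = config.orientation == "maximize"
    sigma = config.resolved_sharing_radius()

    def evaluate(pos_matrix: np.ndarray) -> np.ndarray:
        values = np.array([float(objective(p)) for p in pos_matrix])
        if not np.all(np.isfinite(values)):
            raise ValueError("objective returned a non-finite value")
        return values

    fitness = evaluate(positions)
    evaluations = len(fitness)
    leaders = _rank(positions, fitness, maximize, sigma)

    best_idx = rank_agents(fitness, maximize)[0]
    best_position = positions[best_idx].copy()
    best_fitness = float(fitness[best_idx])

    history = np.empty(config.iterations)
    for t in range(config.iterations):
        a = coefficient_schedule(t, config.iterations)
        for i in range(config.population_size):
            positions[i] = leader_guided_update(
                positions[i], leaders, a, rng,
                config.domain_low, config.domain_high)
        fitness = evaluate(positions)
        evaluations += len(fitness)
        leaders = _rank(positions, fitness, maximize, sigma)
        idx = rank_agents(fitness, maximize)[0]
        if _better(fitness[idx], best_fitness, maximize):
            best_fitness = float(fitness[idx])
            best_position = positions[idx].copy()
        history[t] = best_fitness
        logger.debug("iter=%d best=%.6g a=%.4f", t, best_fitness, a)

    return OptimizationResult(
        best_position=best_position,
        best_fitness=best_fitness,
        history=history,
        evaluations=evaluations,
        leaders=leaders,
    )


def _better(candidate: float, incumbent: float, maximize: bool) -> bool:
    return candidate > incumbent if maximize else candidate < incumbent


def _rank(
    positions: np.ndarray,
    fitness: np.ndarray,
    maximize: bool,
    sigma: float | None,
) -> LeaderTriplet:
    if sigma is None:
        return select_leaders(positions, fitness, fitness,
                              orientation="maximize" if maximize else "minimize")
    m = niche_counts(positions, sigma)
    ranking_fitness = fitness / m if maximize else fitness * m
    return select_leaders(positions, fitness, ranking_fitness,
                          orientation="maximize" if maximize else "minimize")
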