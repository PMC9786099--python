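"""Fitness-sharing niching: penalize crowded agents when ranking leaders.

An agent's niche count ``m_i`` sums a triangular similarity kernel over
every agent (itself included) within radius ``sigma_s``; its shared
fitness is ``F_i / m_i``. Ranking by shared fitness pushes the leader
triplet toward distinct peaks instead of three clones of the best one.
Shared fitness is used only for ranking — raw fitness is what gets
reported and tracked as best-so-far.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def sharing_kernel(d: float, sigma_s: float) -> float:
    """Triangular kernel: ``1 - d/sigma_s`` when ``d < sigma_s``, else 0."""
    if d < 0:
        raise ValueError(f"distance must be nonnegative, got {d}")
    if sigma_s <= 0:
        raise ValueError(f"sigma_s must be positive, got {sigma_s}")
    return 1.0 - d / sigma_s if d < sigma_s else 0.0


def niche_counts(positions: np.ndarray, sigma_s: float) -> np.ndarray:
    """Per-agent crowding mass ``m_i = sum_j kernel(d_ij)``; always >= 1.

    The self-term (d=0, kernel=1) is included, so an isolated agent has
    m = 1 and shared fitness degenerates to raw fitness.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] < 1:
        raise ValueError("at least one agent is required")
    if sigma_s <= 0:
        raise ValueError(f"sigma_s must be positive, got {sigma_s}")
    d = cdist(positions, positions)
    kernel = np.where(d < sigma_s, 1.0 - d / sigma_s, 0.0)
    return kernel.sum(axis=1)


def shared_fitness(fitness: np.ndarray, niche: np.ndarray) -> np.ndarray:
    """Componentwise ``F_i / m_i``."""
    fitness = np.asarray(fitness, dtype=float)
    niche = np.asarray(niche, dtype=float)
    if fitness.shape != niche.shape:
        raise ValueError(
            f"fitness and niche lengths differ: {fitness.shape} vs {niche.shape}")
    if np.any(niche < 1):
        raise ValueError("niche counts must all be >= 1")
    return fitness / niche


def rank_agents(ranking_fitness: np.ndarray, maximize: bool) -> np.ndarray:
    """Indices sorted best-first; ties broken by lower agent index."""
    key = -np.asarray(ranking_fitness, dtype=float) if maximize else ranking_fitness
    return np.argsort(key, kind="stable")


def select_leaders(
    positions: np.ndarray,
    raw_fitness: np.ndarray,
    ranking_fitness: np.ndarray,
    orientation: str = "maximize",
):
    """Top three agents by ranking fitness as an alpha/beta/delta triplet.

    ``ranking_fitness`` is typically the shared fitness (pass the raw
    fitness again to disable niching). The triplet carries raw fitnesses.
    """
    from igwo.gwo import LeaderTriplet  # deferred: gwo imports this module

    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    raw_fitness = np.asarray(raw_fitness, dtype=float)
    if positions.shape[0] < 3:
        raise ValueError(
            f"at least 3 agents are required to pick leaders, got {positions.shape[0]}")
    order = rank_agents(ranking_fitness, orientation == "maximize")
    ia, ib, ic = (int(order[k]) for k in range(3))
    return LeaderTriplet(
        alpha_position=positions[ia].copy(),
        beta_position=positions[ib].copy(),
        delta_position=positions[ic].copy(),
        alpha_fitness=float(raw_fitness[ia]),
        beta_fitness=float(raw_fitness[ib]),
        delta_fitness=float(raw_fitness[ic]),
    )
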