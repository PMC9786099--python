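"""IGWO wrapper feature selection.

Each wolf's continuous position in [0,1]^N is binarized stochastically
into a flag vector (feature j is kept when position_j exceeds a fresh
uniform draw), the flagged subset is scored by an accuracy evaluator, and
the combined fitness trades accuracy against subset size:

    fitness = alpha * P + (1 - alpha) * (N - L) / N

with P the subset's classification accuracy, N the total feature count
and L the number of selected features. The printed source formula is
typographically garbled ("=" where "+" is meant); the form above matches
its stated semantics and the standard wrapper-selection objective.

The loop is GA-seeded and uses fitness sharing on the continuous
positions to keep the leader triplet diverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from igwo.config import OptimizerConfig
from igwo.datasets import LabeledDataset
from igwo.ga import generate_initial_population
from igwo.gwo import coefficient_schedule, leader_guided_update
from igwo.sharing import niche_counts, rank_agents, select_leaders

logger = logging.getLogger(__name__)

#: Fitness assigned to an agent whose flag vector came out empty; the
#: evaluator is never called on an empty subset.
EMPTY_SUBSET_PENALTY = -np.inf


@dataclass
class FlagVector:
    """Binary feature mask; 1 means the feature enters the evaluated subset."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(int)
        if not np.isin(self.flags, (0, 1)).all():
            raise ValueError("flags must be 0/1")

    @property
    def selected_count(self) -> int:
        return int(self.flags.sum())

    @property
    def n_features(self) -> int:
        return int(self.flags.shape[0])

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


@dataclass
class SelectionResult:
    best_flags: FlagVector
    best_fitness: float
    best_accuracy: float
    history: np.ndarray
    selected_feature_names: list[str]
    evaluations: int = 0


def binarize_position(position: np.ndarray, rng: np.random.Generator) -> FlagVector:
    """Stochastic threshold: flag_j = 1 iff position_j > u_j, u_j ~ U[0,1)."""
    position = np.asarray(position, dtype=float)
    if np.any(position < 0) or np.any(position > 1):
        raise ValueError("position components must lie in [0, 1]; clamp upstream")
    return FlagVector((position > rng.random(position.shape[0])).astype(int))


def subset_fitness(P: float, N: int, L: int, alpha: float = 0.99) -> float:
    """``alpha * P + (1 - alpha) * (N - L) / N``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if L < 1:
        raise ValueError("empty feature subset (L = 0) has no defined fitness")
    if L > N:
        raise ValueError(f"selected count L={L} exceeds total features N={N}")
    return alpha * P + (1.0 - alpha) * (N - L) / N


def run_igwo_selection(
    dataset: LabeledDataset,
    evaluator,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
    ga_seeding: bool | None = None,
) -> SelectionResult:
    """Full IGWO selection loop over a labeled dataset.

    ``evaluator`` maps a :class:`FlagVector` to an accuracy in [0, 1]
    (see :func:`igwo.metrics.make_knn_evaluator`). GA seeding is used
    when ``config.ga_generations > 0`` (override via ``ga_seeding``);
    fitness sharing follows ``config.sharing_radius``. Deterministic for
    a fixed config and seed.
    """
    n_features = dataset.n_features
    if n_features < 2:
        raise ValueError("dataset must have at least 2 features")
    if dataset.classes.shape[0] < 2:
        raise ValueError("dataset must have at least 2 classes")
    config = config.with_(dimensionality=n_features, domain_low=0.0, domain_high=1.0,
                          orientation="maximize")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if ga_seeding is None:
        ga_seeding = config.ga_generations > 0

    alpha = config.fitness_alpha
    evaluations = 0

    def position_fitness(position: np.ndarray) -> tuple[float, FlagVector, float]:
        nonlocal evaluations
        flag_vector = binarize_position(position, rng)
        if flag_vector.selected_count == 0:
            return EMPTY_SUBSET_PENALTY, flag_vector, 0.0
        accuracy = float(evaluator(flag_vector))
        evaluations += 1
        return (subset_fitness(accuracy, n_features, flag_vector.selected_count, alpha),
                flag_vector, accuracy)

    if ga_seeding:
        positions = generate_initial_population(
            lambda p: position_fitness(p)[0], config, rng)
    else:
        positions = rng.random((config.population_size, n_features))

    sigma = config.resolved_sharing_radius()

    def evaluate_population():
        triples = [position_fitness(p) for p in positions]
        fitness = np.array([t[0] for t in triples])
        return fitness, [t[1] for t in triples], [t[2] for t in triples]

    def pick_leaders(fitness: np.ndarray):
        if sigma is None:
            return select_leaders(positions, fitness, fitness)
        ranking = fitness / niche_counts(positions, sigma)
        return select_leaders(positions, fitness, ranking)

    fitness, flag_vectors, accuracies = evaluate_population()
    leaders = pick_leaders(fitness)

    best_idx = int(rank_agents(fitness, maximize=True)[0])
    best_fitness = float(fitness[best_idx])
    best_flags = flag_vectors[best_idx]
    best_accuracy = float(accuracies[best_idx])

    history = np.empty(config.iterations)
    for t in range(config.iterations):
        a = coefficient_schedule(t, config.iterations)
        for i in range(config.population_size):
            positions[i] = leader_guided_update(positions[i], leaders, a, rng, 0.0, 1.0)
        fitness, flag_vectors, accuracies = evaluate_population()
        leaders = pick_leaders(fitness)
        idx = int(rank_agents(fitness, maximize=True)[0])
        if fitness[idx] > best_fitness:
            best_fitness = float(fitness[idx])
            best_flags = flag_vectors[idx]
            best_accuracy = float(accuracies[idx])
        history[t] = best_fitness
        logger.debug("iter=%d best=%.6g L=%d", t, best_fitness, best_flags.selected_count)

    names = [dataset.feature_names[i] for i in best_flags.selected_indices()]
    return SelectionResult(
        best_flags=best_flags,
        best_fitness=best_fitness,
        best_accuracy=best_accuracy,
        history=history,
        selected_feature_names=names,
        evaluations=evaluations,
    )
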