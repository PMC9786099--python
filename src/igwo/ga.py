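"""Genetic-algorithm seeding for the wolf pack's starting positions.

A small binary GA — roulette selection, single-point crossover, per-bit
mutation, one elite carried over — evolves chromosomes whose decoded
continuous positions score well on the target objective. The final
generation, decoded, becomes the optimizer's initial population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from igwo.config import OptimizerConfig


@dataclass
class GAConfig:
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    generations: int = 20
    bits_per_dimension: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError(f"crossover_prob must lie in [0, 1], got {self.crossover_prob}")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError(f"mutation_prob must lie in [0, 1], got {self.mutation_prob}")
        if self.generations < 0:
            raise ValueError(f"generations must be >= 0, got {self.generations}")
        if self.bits_per_dimension < 1:
            raise ValueError(f"bits_per_dimension must be >= 1, got {self.bits_per_dimension}")

    @classmethod
    def from_optimizer(cls, config: OptimizerConfig) -> "GAConfig":
        return cls(
            crossover_prob=config.ga_crossover_prob,
            mutation_prob=config.ga_mutation_prob,
            generations=config.ga_generations,
            bits_per_dimension=config.bits_per_dimension,
            seed=config.seed,
        )


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index with probability proportional to its fitness mass."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if np.any(fitnesses < 0):
        raise ValueError("roulette fitnesses must all be nonnegative")
    total = fitnesses.sum()
    if total <= 0:
        raise ValueError("roulette requires at least one strictly positive fitness")
    cumulative = np.cumsum(fitnesses)
    return int(np.searchsorted(cumulative, rng.random() * total, side="right"))


def single_point_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator,
    crossover_prob: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Swap tails at a uniform cut point with probability ``crossover_prob``.

    The cut k is drawn from {1, ..., length-1}; children are
    ``a[:k] ++ b[k:]`` and ``b[:k] ++ a[k:]``. Without crossover the
    children are plain copies.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if parent_a.shape != parent_b.shape:
        raise ValueError(f"parent lengths differ: {parent_a.shape} vs {parent_b.shape}")
    n = parent_a.shape[0]
    if n < 2:
        raise ValueError(f"chromosome length must be >= 2 to cross over, got {n}")
    if rng.random() >= crossover_prob:
        return parent_a.copy(), parent_b.copy()
    k = int(rng.integers(1, n))
    child_a = np.concatenate([parent_a[:k], parent_b[k:]])
    child_b = np.concatenate([parent_b[:k], parent_a[k:]])
    return child_a, child_b


def bit_flip_mutation(
    chromosome: np.ndarray, mutation_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit independently with probability ``mutation_prob``."""
    if not 0.0 <= mutation_prob <= 1.0:
        raise ValueError(f"mutation_prob must lie in [0, 1], got {mutation_prob}")
    chromosome = np.asarray(chromosome)
    flips = rng.random(chromosome.shape[0]) < mutation_prob
    return np.where(flips, 1 - chromosome, chromosome)


def decode_chromosome(
    chromosome: np.ndarray,
    dimensionality: int,
    bits_per_dimension: int,
    domain_low: float = 0.0,
    domain_high: float = 1.0,
) -> np.ndarray:
    """Map each bits_per_dimension block affinely onto the domain.

    A block read as an unsigned integer v becomes
    ``low + v / (2^b - 1) * (high - low)``, so all-zeros decodes to the
    lower bound and all-ones to the upper bound exactly.
    """
    chromosome = np.asarray(chromosome)
    expected = dimensionality * bits_per_dimension
    if chromosome.shape[0] != expected:
        raise ValueError(
            f"chromosome length {chromosome.shape[0]} != "
            f"dimensionality*bits_per_dimension = {expected}")
    blocks = chromosome.reshape(dimensionality, bits_per_dimension)
    weights = 2 ** np.arange(bits_per_dimension - 1, -1, -1, dtype=float)
    values = blocks @ weights
    scale = float(2**bits_per_dimension - 1)
    return domain_low + values / scale * (domain_high - domain_low)


def generate_initial_population(
    objective,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
    ga_config: GAConfig | None = None,
) -> np.ndarray:
    """Evolve a chromosome population and decode it to starting positions.

    Chromosome fitness is ``objective(decode(chromosome))``. Roulette mass
    is a shifted fitness (``f - min + eps`` when maximizing,
    ``max - f + eps`` when minimizing) so selection works for any sign.
    The best chromosome of each generation survives unchanged (elitism).
    With ``generations=0`` this is just a decoded uniform-random
    population.
    """
    if config.population_size < 3:
        raise ValueError("population_size must be >= 3")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if ga_config is None:
        ga_config = GAConfig.from_optimizer(config)

    n_bits = config.dimensionality * ga_config.bits_per_dimension
    pop = rng.integers(0, 2, size=(config.population_size, n_bits))

    def decode(chrom: np.ndarray) -> np.ndarray:
        return decode_chromosome(
            chrom, config.dimensionality, ga_config.bits_per_dimension,
            config.domain_low, config.domain_high)

    maximize = config.orientation == "maximize"
    eps = 1e-12

    def roulette_mass(fitness: np.ndarray) -> np.ndarray:
        # tolerate +-inf sentinels (e.g. empty-subset penalties): they get
        # the minimal mass, finite values keep proportional mass
        finite = np.isfinite(fitness)
        if not finite.any():
            return np.ones_like(fitness)
        worst = fitness[finite].min() if maximize else fitness[finite].max()
        clipped = np.where(finite, fitness, worst)
        return (clipped - clipped.min() + eps if maximize
                else clipped.max() - clipped + eps)

    fitness = np.array([float(objective(decode(c))) for c in pop])
    for _ in range(ga_config.generations):
        mass = roulette_mass(fitness)
        elite = pop[int(np.argmax(fitness) if maximize else np.argmin(fitness))].copy()
        children = [elite]
        while len(children) < config.population_size:
            pa = pop[roulette_select(mass, rng)]
            pb = pop[roulette_select(mass, rng)]
            ca, cb = single_point_crossover(pa, pb, rng, ga_config.crossover_prob)
            children.append(bit_flip_mutation(ca, ga_config.mutation_prob, rng))
            if len(children) < config.population_size:
                children.append(bit_flip_mutation(cb, ga_config.mutation_prob, rng))
        pop = np.array(children)
        fitness = np.array([float(objective(decode(c))) for c in pop])

    return np.array([decode(c) for c in pop])
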