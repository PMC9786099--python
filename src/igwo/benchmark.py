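"""Variant comparison on the planted-feature benchmark.

Runs the full selector (GA seeding + sharing), the plain optimizer
(no seeding, no sharing), a pure GA selector, and a random-subset
baseline at a matched evaluation budget, then tabulates accuracy,
fitness, subset size and recall of the planted features per variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from igwo.config import SHARING_OFF, OptimizerConfig
from igwo.ga import bit_flip_mutation, roulette_select, single_point_crossover
from igwo.metrics import make_knn_evaluator
from igwo.selection import FlagVector, SelectionResult, run_igwo_selection, subset_fitness
from igwo.simulate import FeatureGenSpec, make_feature_dataset

VARIANTS = ("igwo", "gwo", "ga", "random")


def run_variant(
    variant: str,
    dataset,
    evaluator,
    config: OptimizerConfig,
) -> SelectionResult:
    if variant == "igwo":
        return run_igwo_selection(dataset, evaluator, config)
    if variant == "gwo":
        plain = config.with_(sharing_radius=SHARING_OFF, ga_generations=0)
        return run_igwo_selection(dataset, evaluator, plain)
    if variant == "ga":
        return _run_ga_selection(dataset, evaluator, config)
    if variant == "random":
        return _run_random_baseline(dataset, evaluator, config)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def _budget(config: OptimizerConfig) -> int:
    # matches the optimizer's evaluation count: initial pass + one per iteration
    return config.population_size * (config.iterations + 1)


def _score(flags: FlagVector, evaluator, n_features: int, alpha: float) -> tuple[float, float]:
    if flags.selected_count == 0:
        return -np.inf, 0.0
    accuracy = float(evaluator(flags))
    return subset_fitness(accuracy, n_features, flags.selected_count, alpha), accuracy


def _run_random_baseline(dataset, evaluator, config: OptimizerConfig) -> SelectionResult:
    """Best of ``budget`` uniform-random flag vectors (p = 0.5 per feature)."""
    rng = np.random.default_rng(config.seed)
    n = dataset.n_features
    best = None
    history = []
    for _ in range(_budget(config)):
        flags = FlagVector(rng.integers(0, 2, n))
        fitness, accuracy = _score(flags, evaluator, n, config.fitness_alpha)
        if best is None or fitness > best[0]:
            best = (fitness, accuracy, flags)
        history.append(best[0])
    fitness, accuracy, flags = best
    names = [dataset.feature_names[i] for i in flags.selected_indices()]
    return SelectionResult(flags, fitness, accuracy, np.array(history), names,
                           evaluations=_budget(config))


def _run_ga_selection(dataset, evaluator, config: OptimizerConfig) -> SelectionResult:
    """Pure GA over flag bits (one bit per feature) at a matched budget."""
    rng = np.random.default_rng(config.seed)
    n = dataset.n_features
    pop = rng.integers(0, 2, size=(config.population_size, n))

    def score_pop(pop):
        return [ _score(FlagVector(c), evaluator, n, config.fitness_alpha) for c in pop ]

    scored = score_pop(pop)
    best = None
    history = []

    def track(scored, pop):
        nonlocal best
        for (fitness, accuracy), chrom in zip(scored, pop):
            if best is None or fitness > best[0]:
                best = (fitness, accuracy, FlagVector(chrom))
        history.append(best[0])

    track(scored, pop)
    generations = config.iterations  # one generation per optimizer iteration
    eps = 1e-12
    for _ in range(generations):
        fitness = np.array([s[0] for s in scored])
        finite = np.where(np.isfinite(fitness), fitness, np.nanmin(fitness[np.isfinite(fitness)])
                          if np.isfinite(fitness).any() else 0.0)
        mass = finite - finite.min() + eps
        elite = pop[int(np.argmax(finite))].copy()
        children = [elite]
        while len(children) < config.population_size:
            pa = pop[roulette_select(mass, rng)]
            pb = pop[roulette_select(mass, rng)]
            ca, cb = single_point_crossover(pa, pb, rng, config.ga_crossover_prob)
            children.append(bit_flip_mutation(ca, config.ga_mutation_prob, rng))
            if len(children) < config.population_size:
                children.append(bit_flip_mutation(cb, config.ga_mutation_prob, rng))
        pop = np.array(children)
        scored = score_pop(pop)
        track(scored, pop)

    fitness, accuracy, flags = best
    names = [dataset.feature_names[i] for i in flags.selected_indices()]
    return SelectionResult(flags, fitness, accuracy, np.array(history), names,
                           evaluations=config.population_size * (generations + 1))


def run_benchmark(
    config: OptimizerConfig,
    variants=VARIANTS,
    seeds=range(10),
    spec: FeatureGenSpec | None = None,
) -> pd.DataFrame:
    """Per-variant mean/SD of accuracy, fitness, subset size and recall.

    Each seed regenerates the dataset (same seed feeds the generator and
    the optimizer) so variants face identical problems. A failed run is
    recorded in the ``failures`` column and excluded from the means.
    """
    if not variants:
        raise ValueError("at least one variant is required")
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    rows = []
    for variant in variants:
        runs = []
        failures = 0
        for seed in seeds:
            data_spec = spec or FeatureGenSpec()
            data_spec = FeatureGenSpec(**{**data_spec.__dict__, "seed": seed})
            dataset, informative = make_feature_dataset(data_spec)
            evaluator = make_knn_evaluator(dataset, config.k_neighbors)
            try:
                result = run_variant(variant, dataset, evaluator, config.with_(seed=seed))
            except Exception:  # keep remaining runs alive
                failures += 1
                continue
            selected = set(result.best_flags.selected_indices().tolist())
            recall = len(selected & set(informative.tolist())) / len(informative)
            runs.append((result.best_accuracy, result.best_fitness,
                         result.best_flags.selected_count, recall))
        arr = np.array(runs) if runs else np.empty((0, 4))
        row = {"variant": variant, "n_runs": len(runs), "failures": failures}
        for j, name in enumerate(("accuracy", "fitness", "n_selected", "recall")):
            row[f"{name}_mean"] = float(arr[:, j].mean()) if len(runs) else np.nan
            row[f"{name}_sd"] = float(arr[:, j].std(ddof=1)) if len(runs) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
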