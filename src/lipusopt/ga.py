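"""Real-coded genetic algorithm.

Used twice in the analysis: to optimize the surrogate network's initial
weights/thresholds (fitness = negative training MSE) and to search the
continuous stimulation-parameter box (fitness = predicted viability).

The engine maximizes. One generation is roulette-wheel selection on
min-shifted fitness, arithmetic (blend) crossover applied with
probability PC, per-gene Gaussian mutation (sigma = a fraction of the
gene's range) applied with probability PM and clipped to bounds, and
elitist replacement. With at least one elite the best fitness in the
convergence trace is non-decreasing. All randomness flows through the
configured seed, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["GAConfig", "Individual", "ConvergenceTrace", "evolve", "select", "crossover", "mutate"]


@dataclass(frozen=True)
class GAConfig:
    """GA settings; defaults follow the study (population 50, 100
    iterations, PM = 0.1, PC = 0.8)."""

    bounds: object  # (n_genes, 2) array-like of (lower, upper)
    population_size: int = 50
    n_iterations: int = 100
    mutation_prob: float = 0.1
    crossover_prob: float = 0.8
    mutation_sigma_frac: float = 0.1
    elitism_count: int = 1
    rng_seed: object = None

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 1:
            raise ValueError("bounds must be a nonempty (n_genes, 2) array")
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("every gene bound must have lower < upper")
        object.__setattr__(self, "bounds", b)
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must be in [0,1]")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must be in [0,1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")

    @property
    def n_genes(self) -> int:
        return self.bounds.shape[0]

    @property
    def gene_range(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]


@dataclass
class Individual:
    """A candidate gene vector with its fitness (larger is better)."""

    genes: np.ndarray
    fitness: float

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)


@dataclass
class ConvergenceTrace:
    """Per-generation best fitness and best genes (generation 0 is the
    initial population)."""

    best_fitness: np.ndarray
    best_genes: np.ndarray

    @property
    def n_generations(self) -> int:
        return len(self.best_fitness) - 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"generation": np.arange(len(self.best_fitness)),
                           "best_fitness": self.best_fitness})
        for g in range(self.best_genes.shape[1]):
            df[f"gene_{g + 1}"] = self.best_genes[:, g]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_in_bounds(genes: np.ndarray, cfg: GAConfig, who: str) -> None:
    if np.any(genes < cfg.bounds[:, 0]) or np.any(genes > cfg.bounds[:, 1]):
        raise ValueError(f"{who} out of bounds: {genes}")


def select(
    population: np.ndarray,
    fitness: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
    n_parents: int,
) -> np.ndarray:
    """Roulette-wheel (fitness-proportional) selection on min-shifted
    fitness; a flat landscape degrades gracefully to uniform selection."""
    shifted = fitness - fitness.min()
    total = shifted.sum()
    if total > 0:
        p = shifted / total
    else:
        p = np.full(len(population), 1.0 / len(population))
    idx = rng.choice(len(population), size=n_parents, p=p)
    return population[idx].copy()


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic blend with a uniform mixing coefficient u: children are
    u*a + (1-u)*b and its mirror; with probability 1 - PC the parents are
    copied unchanged. Blends of in-bounds parents stay in bounds."""
    _check_in_bounds(parent_a, cfg, "parent_a")
    _check_in_bounds(parent_b, cfg, "parent_b")
    if rng.random() >= cfg.crossover_prob:
        return parent_a.copy(), parent_b.copy()
    u = rng.random()
    child_a = u * parent_a + (1 - u) * parent_b
    child_b = (1 - u) * parent_a + u * parent_b
    return child_a, child_b


def mutate(genes: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene Gaussian perturbation (sigma = mutation_sigma_frac of the
    gene range) applied with probability PM, clipped to bounds."""
    _check_in_bounds(genes, cfg, "individual")
    out = genes.copy()
    mask = rng.random(cfg.n_genes) < cfg.mutation_prob
    if mask.any():
        sigma = cfg.mutation_sigma_frac * cfg.gene_range
        out = out + mask * rng.normal(0.0, 1.0, cfg.n_genes) * sigma
        out = np.clip(out, cfg.bounds[:, 0], cfg.bounds[:, 1])
    return out


def evolve(
    fitness_fn: Callable[[np.ndarray], float],
    cfg: GAConfig,
    initial_genes: np.ndarray | None = None,
) -> tuple[Individual, ConvergenceTrace]:
    """Run the GA and return the best-ever individual and the full trace.

    ``initial_genes`` optionally injects known-good candidates (rows) into
    the otherwise uniform random initial population; with elitism this
    guarantees the result is at least as fit as the best injected
    candidate.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
    pop = rng.uniform(lo, hi, (cfg.population_size, cfg.n_genes))
    if initial_genes is not None:
        seeds = np.atleast_2d(np.asarray(initial_genes, dtype=float))
        k = min(len(seeds), cfg.population_size)
        pop[:k] = np.clip(seeds[:k], lo, hi)

    def evaluate(p: np.ndarray) -> np.ndarray:
        fit = np.empty(len(p))
        for i, genes in enumerate(p):
            v = float(fitness_fn(genes))
            if not np.isfinite(v):
                raise ValueError(f"fitness_fn returned non-finite value {v} at genes {genes}")
            fit[i] = v
        return fit

    fitness = evaluate(pop)
    best_f = [float(fitness.max())]
    best_g = [pop[int(np.argmax(fitness))].copy()]

    for _ in range(cfg.n_iterations):
        order = np.argsort(-fitness, kind="stable")
        elites = pop[order[: cfg.elitism_count]].copy()
        n_children = cfg.population_size - cfg.elitism_count
        parents = select(pop, fitness, cfg, rng, 2 * ((n_children + 1) // 2))
        children = []
        for a, b in zip(parents[0::2], parents[1::2]):
            ca, cb = crossover(a, b, cfg, rng)
            children.append(mutate(ca, cfg, rng))
            children.append(mutate(cb, cfg, rng))
        pop = np.vstack([elites] + [np.asarray(children[:n_children])]) if n_children else elites
        fitness = evaluate(pop)
        best_f.append(float(fitness.max()))
        best_g.append(pop[int(np.argmax(fitness))].copy())

    trace = ConvergenceTrace(np.asarray(best_f), np.asarray(best_g))
    i_best = int(np.argmax(trace.best_fitness))
    best = Individual(trace.best_genes[i_best].copy(), float(trace.best_fitness[i_best]))
    return best, trace
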