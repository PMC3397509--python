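"""Binary genetic algorithm for descriptor-subset selection.

Chromosomes are binary masks over the descriptor columns (1 = selected);
the fitness to *minimize* is the out-of-bag MSE of a random forest fitted
on the masked training descriptors. The generational pipeline is the
classic GA-toolbox one:

* linear-ranking selection (selective pressure 2.0) realized by stochastic
  universal sampling (SUS), with a generation gap of 0.9 (45 offspring for
  a population of 50);
* double-point crossover with probability 0.7 -- two cut points are drawn
  and the enclosed segment exchanged;
* bit-flip mutation at rate 0.7/p (the toolbox default for binary strings);
* elitist reinsertion: offspring replace the worst members of the old
  population, so the population best never worsens.

The RF seed for each fitness evaluation is derived from the GA seed and a
CRC-32 hash of the mask, and evaluations are memoized, so fitness is a
deterministic function of the mask and the GA cannot be misled by forest
sampling noise between identical masks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .config import GAConfig
from .datasets import QSARDataset
from .forest import fit_forest, oob_mse

__all__ = ["GAResult", "FitnessEvaluator", "init_population", "select_parents",
           "double_point_crossover", "mutate", "reinsert", "run_ga"]

_SEED_MOD = 2**31 - 1

Chromosome = np.ndarray  # 1-D boolean mask, at least one bit set


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ensure the non-empty invariant by setting one random bit if needed."""
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(0, mask.size)] = True
    return mask


def init_population(p: int, size: int, rng: np.random.Generator
                    ) -> list[Chromosome]:
    """i.i.d. Bernoulli(0.5) bits; all-zero chromosomes get one bit set."""
    if p < 1:
        raise ValueError("chromosome length must be at least 1")
    if size <= 0:
        raise ValueError("population size must be positive")
    return [_repair(rng.random(p) < 0.5, rng) for _ in range(size)]


class FitnessEvaluator:
    """Memoized OOB-MSE fitness of a descriptor mask on the training split."""

    def __init__(self, X_train: np.ndarray, y_train: np.ndarray,
                 config: GAConfig):
        self.X = np.asarray(X_train, dtype=float)
        self.y = np.asarray(y_train, dtype=float)
        self.config = config
        self._cache: dict[bytes, float] = {}
        self.evaluations = 0
        self.cache_hits = 0

    def rf_seed(self, mask: np.ndarray) -> int:
        h = zlib.crc32(np.packbits(mask).tobytes())
        return (h ^ (self.config.ga_seed * 0x9E3779B1)) % _SEED_MOD

    def __call__(self, mask: Chromosome) -> float:
        if not mask.any():
            raise ValueError("empty descriptor mask has no fitness")
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            self.cache_hits += 1
            return self._cache[key]
        model = fit_forest(self.X[:, mask], self.y,
                           ntree=self.config.rf_ntree,
                           seed=self.rf_seed(mask),
                           min_node_size=self.config.rf_min_node_size)
        val = oob_mse(model)
        self._cache[key] = val
        self.evaluations += 1
        return val

    @property
    def cache_hit_rate(self) -> float:
        total = self.evaluations + self.cache_hits
        return self.cache_hits / total if total else 0.0


def select_parents(population: list[Chromosome], fitnesses: list[float],
                   n_offspring: int, rng: np.random.Generator,
                   pressure: float = 2.0) -> list[Chromosome]:
    """Linear-ranking selection via stochastic universal sampling.

    Fitness is minimized: the best (lowest-MSE) individual receives
    expectation ``pressure`` copies per ``size`` draws, the worst
    ``2 - pressure``; tied fitnesses share the average of their ranks, so a
    population of equal fitnesses is sampled uniformly.
    """
    size = len(population)
    if size == 0 or n_offspring <= 0:
        raise ValueError("need a population and a positive offspring count")
    f = np.asarray(fitnesses, dtype=float)
    # rank 0 = worst (highest MSE) ... size-1 = best; ties averaged
    ranks = rankdata(-f, method="average") - 1.0
    if size == 1:
        expectation = np.array([float(n_offspring)])
    else:
        expectation = (2.0 - pressure) + 2.0 * (pressure - 1.0) * ranks / (size - 1)
    total = expectation.sum()
    spacing = total / n_offspring
    start = rng.uniform(0.0, spacing)
    pointers = start + spacing * np.arange(n_offspring)
    cumulative = np.cumsum(expectation)
    picks = np.searchsorted(cumulative, pointers, side="right")
    picks = np.clip(picks, 0, size - 1)
    return [population[i].copy() for i in picks]


def double_point_crossover(a: Chromosome, b: Chromosome, prob: float,
                           rng: np.random.Generator
                           ) -> tuple[Chromosome, Chromosome]:
    """Exchange the segment between two cut points with probability ``prob``."""
    if a.size != b.size:
        raise ValueError("parent chromosomes must have equal length")
    child_a, child_b = a.copy(), b.copy()
    p = a.size
    if p >= 3 and rng.random() < prob:
        c1, c2 = np.sort(rng.choice(np.arange(1, p), size=2, replace=False))
        child_a[c1:c2], child_b[c1:c2] = b[c1:c2].copy(), a[c1:c2].copy()
    return _repair(child_a, rng), _repair(child_b, rng)


def mutate(mask: Chromosome, rate: float, rng: np.random.Generator
           ) -> Chromosome:
    """Flip each bit independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    flips = rng.random(mask.size) < rate
    return _repair(mask ^ flips, rng)


def reinsert(old_population: list[Chromosome], old_fitnesses: list[float],
             offspring: list[Chromosome], offspring_fitnesses: list[float]
             ) -> tuple[list[Chromosome], list[float]]:
    """Elitist reinsertion: offspring replace the worst old individuals."""
    if len(offspring) > len(old_population):
        raise ValueError("more offspring than population slots")
    n_keep = len(old_population) - len(offspring)
    # stable sort: ties survive in age order (older first)
    order = np.argsort(np.asarray(old_fitnesses), kind="stable")[:n_keep]
    pop = [old_population[i] for i in order] + list(offspring)
    fit = [old_fitnesses[i] for i in order] + list(offspring_fitnesses)
    return pop, fit


@dataclass
class GAResult:
    """Outcome of a GA run: the best-ever mask and the search history."""

    best_mask: Chromosome
    best_fitness: float
    history: list[tuple[float, float]] = field(default_factory=list)  # (best, mean)
    evaluations: int = 0
    cache_hit_rate: float = 0.0
    descriptor_names: list[str] | None = None

    @property
    def selected_descriptors(self) -> list[str]:
        names = self.descriptor_names or [f"X{j}"
                                          for j in range(self.best_mask.size)]
        return [n for n, b in zip(names, self.best_mask) if b]


def run_ga(dataset: QSARDataset, config: GAConfig | None = None) -> GAResult:
    """Evolve descriptor masks for ``config.max_generations`` generations.

    Only training-split compounds are used for fitness. Termination is the
    fixed generation count; the result is bit-identical for identical
    (dataset, config) thanks to the seeded RNG and mask-derived RF seeds.
    """
    cfg = config or GAConfig()
    X_train, y_train = dataset.training_xy()
    p = X_train.shape[1]
    rng = np.random.default_rng(cfg.ga_seed)
    evaluator = FitnessEvaluator(X_train, y_train, cfg)
    rate = cfg.resolved_mutation_rate(p)

    population = init_population(p, cfg.population_size, rng)
    fitnesses = [evaluator(m) for m in population]
    best_i = int(np.argmin(fitnesses))
    best_mask, best_fit = population[best_i].copy(), fitnesses[best_i]
    history: list[tuple[float, float]] = []

    for _ in range(cfg.max_generations):
        parents = select_parents(population, fitnesses, cfg.n_offspring, rng,
                                 cfg.selective_pressure)
        offspring: list[Chromosome] = []
        for i in range(0, len(parents) - 1, 2):
            offspring.extend(double_point_crossover(parents[i], parents[i + 1],
                                                    cfg.crossover_prob, rng))
        if len(parents) % 2:              # odd gap: last parent passes through
            offspring.append(parents[-1].copy())
        offspring = [mutate(m, rate, rng) for m in offspring[:cfg.n_offspring]]
        off_fit = [evaluator(m) for m in offspring]
        population, fitnesses = reinsert(population, fitnesses,
                                         offspring, off_fit)
        gen_best = int(np.argmin(fitnesses))
        if fitnesses[gen_best] < best_fit:
            best_fit = fitnesses[gen_best]
            best_mask = population[gen_best].copy()
        history.append((best_fit, float(np.mean(fitnesses))))

    return GAResult(best_mask=best_mask, best_fitness=best_fit,
                    history=history, evaluations=evaluator.evaluations,
                    cache_hit_rate=evaluator.cache_hit_rate,
                    descriptor_names=list(dataset.matrix.descriptor_names))
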