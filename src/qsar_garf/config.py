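"""Run configuration for the GA-RF pipeline.

Defaults collect the study's printed constants: the 85% sparse-zero cutoff,
the 0.75 correlation cutoff, the 6x6 Kohonen map, GA population 50 over 200
generations with generation gap 0.9 and double-point crossover probability
0.7, forests of 500 trees, and 500 Y-randomization rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["GAConfig", "PipelineConfig"]


@dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor-subset search.

    ``mutation_rate=None`` resolves to 0.7/p (the classic GA-toolbox default
    for binary chromosomes of length p). Fitness is the out-of-bag MSE of a
    random forest with ``rf_ntree`` trees fitted on the masked descriptors;
    the per-mask RF seed is derived from ``ga_seed`` and a hash of the mask
    so fitness is a deterministic function of the mask.
    """

    population_size: int = 50
    max_generations: int = 200
    generation_gap: float = 0.9
    crossover_prob: float = 0.7
    mutation_rate: Optional[float] = None
    selective_pressure: float = 2.0
    rf_ntree: int = 100
    rf_min_node_size: int = 5
    ga_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.max_generations <= 0:
            raise ValueError("population_size and max_generations must be positive")
        if not 0.0 < self.generation_gap <= 1.0:
            raise ValueError("generation_gap must be in (0, 1]")
        for name in ("crossover_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")

    def resolved_mutation_rate(self, p: int) -> float:
        return self.mutation_rate if self.mutation_rate is not None else 0.7 / p

    @property
    def n_offspring(self) -> int:
        return int(round(self.generation_gap * self.population_size))


@dataclass
class PipelineConfig:
    """End-to-end settings: filters, SOM split, GA, final forest, checks."""

    # descriptor filters
    zero_fraction: float = 0.85
    freq_ratio_cutoff: float = 19.0
    unique_percent_cutoff: float = 10.0
    corr_cutoff: float = 0.75
    # SOM split
    som_rows: int = 6
    som_cols: int = 6
    som_iterations: Optional[int] = None  # default 500 * n_units
    test_size: Optional[int] = None       # default round(n / 3)
    # GA
    ga: GAConfig = field(default_factory=GAConfig)
    # final forest
    rf_ntree: int = 500
    rf_mtry: Optional[int] = None         # default floor(p_selected / 3)
    rf_min_node_size: int = 5
    # Y-randomization
    yrand_rounds: int = 500
    # global RNG seed (SOM training, split sampling, final forest)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must be in (0, 1]")
        if not 0.0 < self.corr_cutoff < 1.0:
            raise ValueError("corr_cutoff must be in (0, 1)")
        if self.som_rows <= 0 or self.som_cols <= 0:
            raise ValueError("SOM grid dimensions must be positive")
        if self.yrand_rounds < 0:
            raise ValueError("yrand_rounds must be non-negative")
        if isinstance(self.ga, dict):
            self.ga = GAConfig(**self.ga)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
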