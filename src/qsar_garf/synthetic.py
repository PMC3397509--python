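"""Seeded generators for descriptor matrices with known ground truth.

Real descriptor tables mix a small informative core with redundant,
near-constant and sparse columns; the generator reproduces that statistical
structure so preprocessing, SOM splitting, GA recovery, forest tuning and
Y-randomization are all testable with an analytic answer key:

* informative columns ~ N(0, 1) driving a linear activity
  y = intercept + X beta + eps, eps ~ N(0, noise_sd^2), with the intercept
  defaulting to 6.0 so activities sit on a realistic pIC50 scale;
* correlated decoys: near-duplicates of informative columns at a specified
  population correlation;
* sparse decoys: zero-inflated columns with an exact zero fraction (so the
  sparse-zero filter's decision is deterministic);
* constant columns; and pure-noise fillers for the rest.

With independent standard-normal informative columns the population R^2 is
``sum(beta^2) / (sum(beta^2) + noise_sd^2)``, so acceptance bounds are
analytic. The default specification -- 150 compounds, 100 descriptors, 10
informative with unit coefficients, noise_sd = sqrt(2.5) -- has population
R^2 = 0.8: strong enough for subset selection to be discriminating, small
enough for minutes-scale testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ActivityVector, DescriptorMatrix, QSARDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate_qsar",
           "generate_clustered"]

INFORMATIVE, NOISE, SPARSE, CORRELATED, CONSTANT = (
    "informative", "noise", "sparse", "correlated", "constant")

DEFAULT_NOISE_SD = float(np.sqrt(2.5))   # population R^2 = 0.8 with 10 unit betas


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic QSAR problem (a pure function of itself)."""

    n_compounds: int = 150
    n_descriptors: int = 100
    n_informative: int = 10
    beta: np.ndarray | None = None        # default: all ones
    intercept: float = 6.0                # pIC50-like baseline
    noise_sd: float = DEFAULT_NOISE_SD
    n_sparse_columns: int = 10
    sparse_zero_fraction: float = 0.95
    n_correlated_pairs: int = 10
    correlated_r: float = 0.9
    n_constant_columns: int = 3
    # clustered-matrix generation (SOM tests)
    n_clusters: int = 3
    cluster_separation: float = 10.0
    cluster_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta is None:
            self.beta = np.ones(self.n_informative)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.size != self.n_informative:
            raise ValueError("beta must have one coefficient per informative "
                             "descriptor")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.sparse_zero_fraction < 1.0:
            raise ValueError("sparse_zero_fraction must be in (0, 1)")

    @property
    def n_structured(self) -> int:
        return (self.n_informative + self.n_sparse_columns
                + self.n_correlated_pairs + self.n_constant_columns)

    @property
    def population_r2(self) -> float:
        signal = float(np.sum(self.beta ** 2))
        total = signal + self.noise_sd ** 2
        return signal / total if total > 0 else float("nan")


@dataclass
class GroundTruth:
    """Answer key: every column's role and coefficient."""

    roles: dict[str, str]
    beta: dict[str, float]                # informative columns only
    population_r2: float
    correlated_partner: dict[str, str] = field(default_factory=dict)

    @property
    def informative(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == INFORMATIVE]

    def recall(self, selected: list[str]) -> float:
        """Fraction of informative signals recovered by ``selected``.

        A signal counts as recovered if the mask contains the informative
        column itself or one of its correlated near-duplicates -- the
        standard accounting for redundant feature groups, where either
        member carries the signal.
        """
        inf = self.informative
        if not inf:
            return float("nan")
        sel = set(selected)
        proxies: dict[str, set[str]] = {n: {n} for n in inf}
        for decoy, src in self.correlated_partner.items():
            proxies[src].add(decoy)
        return sum(1 for n in inf if proxies[n] & sel) / len(inf)

    def strict_recall(self, selected: list[str]) -> float:
        """Fraction of informative columns themselves present in ``selected``."""
        inf = set(self.informative)
        return len(inf & set(selected)) / len(inf) if inf else float("nan")

    def precision(self, selected: list[str]) -> float:
        if not selected:
            return float("nan")
        inf = set(self.informative)
        return len(inf & set(selected)) / len(selected)


def generate_qsar(spec: SyntheticSpec) -> tuple[QSARDataset, GroundTruth]:
    """Generate a dataset with the spec's column mix and linear activity."""
    if spec.n_structured > spec.n_descriptors:
        raise ValueError(
            f"{spec.n_structured} structured columns exceed n_descriptors "
            f"{spec.n_descriptors}")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    k = spec.n_informative

    X = np.empty((n, p))
    roles = [NOISE] * p
    names = [f"D{j + 1:03d}" for j in range(p)]
    order = rng.permutation(p)            # scatter the structured columns
    slots = list(order)

    inf_idx = [slots.pop() for _ in range(k)]
    X_inf = rng.standard_normal((n, k))
    for col, j in enumerate(inf_idx):
        X[:, j] = X_inf[:, col]
        roles[j] = INFORMATIVE

    partner: dict[str, str] = {}
    corr_idx = [slots.pop() for _ in range(spec.n_correlated_pairs)]
    for m, j in enumerate(corr_idx):
        src = m % max(k, 1)
        r = spec.correlated_r
        X[:, j] = r * X_inf[:, src] + np.sqrt(1 - r * r) * rng.standard_normal(n)
        roles[j] = CORRELATED
        partner[names[j]] = names[inf_idx[src]]

    n_zero = int(round(spec.sparse_zero_fraction * n))
    for j in [slots.pop() for _ in range(spec.n_sparse_columns)]:
        col = rng.standard_normal(n)
        col[rng.choice(n, size=n_zero, replace=False)] = 0.0
        X[:, j] = col
        roles[j] = SPARSE

    for j in [slots.pop() for _ in range(spec.n_constant_columns)]:
        X[:, j] = 1.0
        roles[j] = CONSTANT

    for j in slots:
        X[:, j] = rng.standard_normal(n)

    y = spec.intercept + X_inf @ spec.beta + spec.noise_sd * rng.standard_normal(n)

    ids = [f"C{i + 1:04d}" for i in range(n)]
    dataset = QSARDataset(DescriptorMatrix(ids, names, X),
                          ActivityVector(ids, y))
    truth = GroundTruth(
        roles=dict(zip(names, roles)),
        beta={names[j]: float(spec.beta[c]) for c, j in enumerate(inf_idx)},
        population_r2=spec.population_r2,
        correlated_partner=partner,
    )
    return dataset, truth


def generate_clustered(spec: SyntheticSpec
                       ) -> tuple[DescriptorMatrix, np.ndarray]:
    """Gaussian blobs in descriptor space, for map-splitting tests.

    Adjacent cluster centroids sit ``cluster_separation`` apart along the
    main diagonal, so the separation survives per-descriptor
    standardization; returns the matrix and the per-compound cluster labels.
    """
    if spec.n_clusters < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    labels = np.arange(n) % spec.n_clusters
    direction = np.full(p, 1.0 / np.sqrt(p))
    centers = (np.arange(spec.n_clusters)[:, None]
               * spec.cluster_separation * direction)
    X = centers[labels] + spec.cluster_sd * rng.standard_normal((n, p))
    ids = [f"C{i + 1:04d}" for i in range(n)]
    names = [f"D{j + 1:03d}" for j in range(p)]
    return DescriptorMatrix(ids, names, X), labels
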