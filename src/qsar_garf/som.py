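"""Kohonen self-organizing map for rational train/test splitting.

A small map (6x6 = 36 units by default) is trained on the standardized
descriptor space; every compound is placed on its best-matching unit (BMU),
and the test set is then drawn per unit proportionally to unit occupancy.
This enforces the two properties a rational split should have: test
compounds lie near training compounds in descriptor space, and the two sets
jointly cover the occupied map.

The SOM is trained online: at each step a random compound is presented, its
BMU located by Euclidean distance, and all codebook vectors are pulled
toward it with a Gaussian neighborhood whose radius decays linearly from
max(rows, cols)/2 to 1 while the learning rate decays from 0.5 to 0.01.
Descriptors are standardized to zero mean / unit variance for SOM training
only (distance-based placement needs comparable scales; the forests later
use raw values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import TRAIN, TEST, DescriptorMatrix

__all__ = ["SOMGrid", "SplitAssignment", "train_som", "map_to_bmu",
           "split_by_som"]

LEARNING_RATE_START, LEARNING_RATE_END = 0.5, 0.01


@dataclass
class SOMGrid:
    """A trained map: codebook vectors plus the standardization parameters."""

    rows: int
    cols: int
    codebook: np.ndarray        # (rows * cols, p), in standardized space
    mean_: np.ndarray           # (p,)
    scale_: np.ndarray          # (p,), 1.0 where the input column was constant
    n_iterations: int
    seed: int

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean_) / self.scale_


@dataclass
class SplitAssignment:
    """Per-compound BMU index and train/test label."""

    compound_ids: list[str]
    bmu: list[int]
    label: list[str]

    def __post_init__(self) -> None:
        if not len(self.compound_ids) == len(self.bmu) == len(self.label):
            raise ValueError("compound_ids, bmu and label must align")

    @property
    def n_test(self) -> int:
        return sum(1 for s in self.label if s == TEST)


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def train_som(matrix: DescriptorMatrix, n_iterations: int | None = None,
              seed: int = 0, rows: int = 6, cols: int = 6) -> SOMGrid:
    """Train a rows x cols SOM on the standardized descriptor matrix.

    ``n_iterations`` defaults to 500 presentations per map unit. Training is
    deterministic for a fixed seed.
    """
    if matrix.n_compounds < 2:
        raise ValueError("SOM training needs at least 2 compounds")
    X = matrix.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.all(sd == 0.0):
        raise ValueError("descriptor matrix is constant; SOM is undefined")
    scale = np.where(sd == 0.0, 1.0, sd)
    Z = (X - mean) / scale

    n_units = rows * cols
    if n_iterations is None:
        n_iterations = 500 * n_units
    rng = np.random.default_rng(seed)
    # initialize codebook from random data rows (with replacement so small
    # datasets still work)
    codebook = Z[rng.integers(0, Z.shape[0], n_units)].astype(float).copy()
    coords = _grid_coords(rows, cols)

    radius_start, radius_end = max(rows, cols) / 2.0, 1.0
    denom = max(n_iterations - 1, 1)
    for t in range(n_iterations):
        frac = t / denom
        lr = LEARNING_RATE_START + frac * (LEARNING_RATE_END - LEARNING_RATE_START)
        radius = radius_start + frac * (radius_end - radius_start)
        x = Z[rng.integers(0, Z.shape[0])]
        bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
        grid_d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
        h = np.exp(-grid_d2 / (2.0 * radius * radius))
        codebook += (lr * h)[:, None] * (x - codebook)

    return SOMGrid(rows, cols, codebook, mean, scale, n_iterations, seed)


def map_to_bmu(grid: SOMGrid, matrix: DescriptorMatrix) -> list[int]:
    """Best-matching unit per compound (ties resolve to the lowest index)."""
    if matrix.n_descriptors != grid.codebook.shape[1]:
        raise ValueError(
            f"descriptor dimensionality {matrix.n_descriptors} does not match "
            f"the trained map ({grid.codebook.shape[1]})")
    Z = grid.standardize(matrix.values)
    d2 = ((Z[:, None, :] - grid.codebook[None, :, :]) ** 2).sum(axis=2)
    return [int(b) for b in np.argmin(d2, axis=1)]


def split_by_som(matrix: DescriptorMatrix, bmu: list[int], test_size: int,
                 seed: int = 0) -> SplitAssignment:
    """Draw a test set proportionally to SOM unit occupancy.

    Per occupied unit, the test quota is ``test_size * occupancy / n``
    rounded by largest remainder so the quotas sum to ``test_size`` exactly,
    under the coverage rule that every unit keeps at least one training
    compound (singleton units contribute nothing to the test set). Within a
    unit the quota is sampled uniformly at random; changing the seed changes
    only this within-unit sampling.
    """
    n = len(bmu)
    if n != matrix.n_compounds:
        raise ValueError("bmu list must cover every compound")
    if not 0 < test_size < n:
        raise ValueError(f"test_size must be in (0, {n}); got {test_size}")

    units = sorted(set(bmu))
    members = {u: [i for i, b in enumerate(bmu) if b == u] for u in units}
    cap = {u: max(len(members[u]) - 1, 0) for u in units}
    if sum(cap.values()) < test_size:
        raise ValueError(
            "test_size unreachable under the train-coverage rule: at most "
            f"{sum(cap.values())} compounds can be spared for the test set")

    exact = {u: test_size * len(members[u]) / n for u in units}
    quota = {u: min(int(np.floor(exact[u])), cap[u]) for u in units}
    # distribute the remainder by largest fractional part, then by capacity
    while sum(quota.values()) < test_size:
        candidates = [u for u in units if quota[u] < cap[u]]
        candidates.sort(key=lambda u: (-(exact[u] - np.floor(exact[u])), u))
        for u in candidates:
            if sum(quota.values()) >= test_size:
                break
            quota[u] += 1

    rng = np.random.default_rng(seed)
    label = [TRAIN] * n
    for u in units:
        take = quota[u]
        if take == 0:
            continue
        chosen = rng.choice(members[u], size=take, replace=False)
        for i in chosen:
            label[int(i)] = TEST
    return SplitAssignment(list(matrix.compound_ids), list(bmu), label)
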