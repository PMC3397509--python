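"""Descriptor-matrix filters applied before modelling.

Three filters run in a fixed order, each logging what it removed and why:

1. sparse-zero: drop descriptors whose fraction of exact zeros exceeds a
   cutoff (default 0.85);
2. near-zero variance: drop constant descriptors, and descriptors whose
   most-frequent/second-most-frequent value-count ratio exceeds a cutoff
   (default 19, i.e. 95/5) while the percentage of distinct values is below
   a cutoff (default 10%);
3. pairwise correlation: greedily drop one member of every descriptor pair
   with absolute Pearson correlation above a cutoff (default 0.75) until no
   such pair survives.

Filter 2 is the frequency-ratio / unique-percent rule standard in QSAR
preprocessing; filter 3 drops, from the currently worst pair, the member
with the larger mean absolute correlation to all remaining descriptors
(ties broken toward the later column in input order), so the result is
deterministic and order-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .datasets import DescriptorMatrix

__all__ = [
    "FilterReport",
    "filter_sparse_zero",
    "filter_near_zero_variance",
    "filter_correlated",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

SPARSE_ZERO = "sparse_zero"
NEAR_ZERO_VARIANCE = "near_zero_variance"
CORRELATED = "correlated"


@dataclass
class FilterReport:
    """Provenance of a filtering step: what was removed, what was kept."""

    removed: list[tuple[str, str, str]] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)

    def merge(self, later: "FilterReport") -> "FilterReport":
        """Compose with a report from a subsequent stage."""
        return FilterReport(removed=self.removed + later.removed,
                            kept=list(later.kept))

    @property
    def removed_names(self) -> list[str]:
        return [name for name, _, _ in self.removed]


def _subset(matrix: DescriptorMatrix, keep_idx: list[int]) -> DescriptorMatrix:
    return DescriptorMatrix(
        list(matrix.compound_ids),
        [matrix.descriptor_names[i] for i in keep_idx],
        matrix.values[:, keep_idx].copy(),
    )


def _guard_nonempty(kept: list[int], rule: str) -> None:
    if not kept:
        raise ValueError(
            f"{rule} filter removed every descriptor; relax the threshold")


def filter_sparse_zero(matrix: DescriptorMatrix,
                       zero_fraction: float = 0.85
                       ) -> tuple[DescriptorMatrix, FilterReport]:
    """Drop descriptors whose zero fraction strictly exceeds ``zero_fraction``."""
    if matrix.n_descriptors == 0 or matrix.n_compounds == 0:
        raise ValueError("empty descriptor matrix")
    n = matrix.n_compounds
    frac = (matrix.values == 0.0).sum(axis=0) / n
    keep, removed = [], []
    for j, name in enumerate(matrix.descriptor_names):
        if frac[j] > zero_fraction:
            removed.append((name, SPARSE_ZERO,
                            f"zero fraction {frac[j]:.3f} > {zero_fraction}"))
        else:
            keep.append(j)
    _guard_nonempty(keep, SPARSE_ZERO)
    out = _subset(matrix, keep)
    return out, FilterReport(removed, list(out.descriptor_names))


def filter_near_zero_variance(matrix: DescriptorMatrix,
                              freq_ratio_cutoff: float = 19.0,
                              unique_percent_cutoff: float = 10.0
                              ) -> tuple[DescriptorMatrix, FilterReport]:
    """Drop constant and near-zero-variance descriptors."""
    if matrix.n_descriptors == 0 or matrix.n_compounds == 0:
        raise ValueError("empty descriptor matrix")
    n = matrix.n_compounds
    keep, removed = [], []
    for j, name in enumerate(matrix.descriptor_names):
        col = matrix.values[:, j]
        _, counts = np.unique(col, return_counts=True)
        if len(counts) == 1:
            removed.append((name, NEAR_ZERO_VARIANCE, "constant column"))
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * len(counts) / n
        if freq_ratio > freq_ratio_cutoff and unique_pct < unique_percent_cutoff:
            removed.append((name, NEAR_ZERO_VARIANCE,
                            f"freq ratio {freq_ratio:.1f} > {freq_ratio_cutoff}, "
                            f"unique {unique_pct:.1f}% < {unique_percent_cutoff}%"))
        else:
            keep.append(j)
    _guard_nonempty(keep, NEAR_ZERO_VARIANCE)
    out = _subset(matrix, keep)
    return out, FilterReport(removed, list(out.descriptor_names))


def max_abs_offdiag_correlation(values: np.ndarray) -> float:
    """Largest off-diagonal |Pearson r| of a matrix's columns (0 if p < 2)."""
    if values.shape[1] < 2:
        return 0.0
    r = np.abs(np.corrcoef(values, rowvar=False))
    np.fill_diagonal(r, 0.0)
    return float(r.max())


def filter_correlated(matrix: DescriptorMatrix, cutoff: float = 0.75
                      ) -> tuple[DescriptorMatrix, FilterReport]:
    """Greedy elimination of descriptor pairs with |Pearson r| above ``cutoff``.

    While any surviving pair exceeds the cutoff, the pair with the largest
    |r| is located and the member with the larger mean absolute correlation
    to all remaining descriptors is dropped (ties: drop the later column in
    input order). Guarantees max off-diagonal |r| <= cutoff on output.
    """
    if matrix.n_compounds < 2:
        raise ValueError("correlation filter needs at least 2 compounds")
    sd = matrix.values.std(axis=0)
    zero_var = np.where(sd == 0.0)[0]
    if zero_var.size:
        raise ValueError(
            "zero-variance descriptor(s) must be filtered before the "
            "correlation filter: "
            + ", ".join(matrix.descriptor_names[j] for j in zero_var))

    corr = np.abs(np.corrcoef(matrix.values, rowvar=False))
    if matrix.n_descriptors == 1:
        corr = corr.reshape(1, 1)
    np.fill_diagonal(corr, 0.0)
    alive = list(range(matrix.n_descriptors))
    removed: list[tuple[str, str, str]] = []
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        worst = float(sub.max())
        if worst <= cutoff:
            break
        a_loc, b_loc = map(int, np.unravel_index(int(sub.argmax()), sub.shape))
        mean_a = sub[a_loc].sum() / (len(alive) - 1)
        mean_b = sub[b_loc].sum() / (len(alive) - 1)
        if mean_a > mean_b:
            drop_loc = a_loc
        elif mean_b > mean_a:
            drop_loc = b_loc
        else:
            drop_loc = max(a_loc, b_loc)  # tie: later column in input order
        other_loc = b_loc if drop_loc == a_loc else a_loc
        drop, other = alive[drop_loc], alive[other_loc]
        removed.append((matrix.descriptor_names[drop], CORRELATED,
                        f"|r| = {worst:.3f} with {matrix.descriptor_names[other]}"
                        f" > {cutoff}"))
        alive.pop(drop_loc)
    _guard_nonempty(alive, CORRELATED)
    out = _subset(matrix, alive)
    assert max_abs_offdiag_correlation(out.values) <= cutoff + 1e-12
    return out, FilterReport(removed, list(out.descriptor_names))


def preprocess_pipeline(matrix: DescriptorMatrix,
                        config: PipelineConfig | None = None
                        ) -> tuple[DescriptorMatrix, FilterReport]:
    """Run the three filters in order and merge their reports."""
    cfg = config or PipelineConfig()
    if matrix.n_descriptors == 0 or matrix.n_compounds == 0:
        raise ValueError("empty descriptor matrix")
    logger.info("preprocess: %d descriptors in", matrix.n_descriptors)
    m1, r1 = filter_sparse_zero(matrix, cfg.zero_fraction)
    logger.info("after sparse-zero filter: %d", m1.n_descriptors)
    m2, r2 = filter_near_zero_variance(m1, cfg.freq_ratio_cutoff,
                                       cfg.unique_percent_cutoff)
    logger.info("after near-zero-variance filter: %d", m2.n_descriptors)
    m3, r3 = filter_correlated(m2, cfg.corr_cutoff)
    logger.info("after correlation filter: %d", m3.n_descriptors)
    return m3, r1.merge(r2).merge(r3)
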