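"""Random-forest regression with explicit out-of-bag (OOB) machinery.

Individual trees are unpruned CART regression trees
(:class:`sklearn.tree.DecisionTreeRegressor`); the bagging loop, OOB
aggregation, permutation importance and the tuning experiments are
implemented here because they need per-tree bootstrap bookkeeping that the
stock ensemble wrappers do not expose:

* OOB prediction for compound i aggregates only trees whose bootstrap
  excluded i -- the forest's built-in cross-validation surrogate;
* %IncMSE permutation importance follows the classic definition: per tree,
  the increase in OOB MSE after permuting one descriptor, averaged over
  trees and normalized by its standard error;
* IncNodePurity is the total decrease in node sum-of-squares attributed to
  splits on a descriptor (the regression analogue of mean decrease Gini);
* the ntree convergence curve evaluates prefixes of a single fitted forest
  rather than refitting at every tree count.

``mtry`` is the number of descriptors sampled as split candidates at each
node; the regression default is floor(p / 3) (never below 1). Nodes with
``min_node_size`` compounds or fewer are not split further (default 5, the
standard regression forest setting), but resulting leaves may be smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["ForestModel", "TuningResult", "default_mtry", "fit_forest",
           "oob_mse", "oob_r2", "variable_importance", "mtry_sweep",
           "ntree_curve"]

_SEED_MOD = 2**31 - 1


def default_mtry(p: int) -> int:
    """Regression default: one third of the descriptor count, at least 1."""
    return max(1, p // 3)


@dataclass
class ForestModel:
    """A fitted bagged ensemble of unpruned regression trees."""

    ntree: int
    mtry: int
    seed: int
    trees: list = field(repr=False)
    bootstrap_idx: list = field(repr=False)   # per-tree in-bag sample indices
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    descriptor_names: list[str] | None = None

    # filled in by fit_forest
    oob_prediction: np.ndarray = field(default=None, repr=False)
    oob_count: np.ndarray = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def oob_missing(self) -> np.ndarray:
        """Boolean mask of samples that were in-bag for every tree."""
        return self.oob_count == 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        for t in self.trees:
            out += t.predict(X)
        return out / len(self.trees)


def _tree_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _SEED_MOD))


def fit_forest(X: np.ndarray, y: np.ndarray, ntree: int = 500,
               mtry: int | None = None, seed: int = 0,
               min_node_size: int = 5,
               descriptor_names: list[str] | None = None) -> ForestModel:
    """Fit a bagged forest of unpruned CART regression trees.

    Deterministic for a fixed seed: one RNG stream drives both the bootstrap
    draws and the per-tree split-candidate sampling seeds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValueError("descriptor matrix has no columns")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if mtry is None:
        mtry = default_mtry(p)
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}]; got {mtry}")
    if ntree < 1:
        raise ValueError("ntree must be positive")

    rng = np.random.default_rng(seed)
    trees, boots = [], []
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    for _ in range(ntree):
        idx = rng.integers(0, n, n)
        tree = DecisionTreeRegressor(max_features=mtry,
                                     min_samples_split=max(2, min_node_size), min_samples_leaf=1,
                                     random_state=_tree_seed(rng))
        tree.fit(X[idx], y[idx])
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if oob.any():
            oob_sum[oob] += tree.predict(X[oob])
            oob_cnt[oob] += 1
        trees.append(tree)
        boots.append(idx)

    oob_pred = np.full(n, np.nan)
    has = oob_cnt > 0
    oob_pred[has] = oob_sum[has] / oob_cnt[has]
    return ForestModel(ntree=ntree, mtry=mtry, seed=seed, trees=trees,
                       bootstrap_idx=boots, X=X, y=y,
                       descriptor_names=descriptor_names,
                       oob_prediction=oob_pred, oob_count=oob_cnt)


def oob_mse(model: ForestModel) -> float:
    """Mean squared error of the OOB predictions against the training y."""
    if model.oob_missing.any():
        flagged = np.where(model.oob_missing)[0].tolist()
        raise ValueError(
            f"samples without an OOB prediction (in-bag in every tree): "
            f"{flagged}; increase ntree")
    return float(np.mean((model.y - model.oob_prediction) ** 2))


def oob_r2(model: ForestModel) -> float:
    """Squared Pearson correlation of y with its OOB predictions.

    Returns NaN when either vector is constant (undefined correlation).
    """
    if model.oob_missing.any():
        raise ValueError("samples without an OOB prediction; increase ntree")
    y, yhat = model.y, model.oob_prediction
    if y.std() == 0.0 or yhat.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def _node_purity_decrease(tree: DecisionTreeRegressor, p: int) -> np.ndarray:
    """Per-feature total decrease in node sum-of-squares for one tree."""
    t = tree.tree_
    out = np.zeros(p)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:      # leaf
            continue
        ss = t.weighted_n_node_samples[node] * t.impurity[node]
        ss_children = (t.weighted_n_node_samples[left] * t.impurity[left]
                       + t.weighted_n_node_samples[right] * t.impurity[right])
        out[t.feature[node]] += ss - ss_children
    return out


def variable_importance(model: ForestModel, seed: int | None = None
                        ) -> pd.DataFrame:
    """Permutation (%IncMSE) and node-purity (IncNodePurity) importances.

    %IncMSE: per tree, the OOB MSE after permuting descriptor j minus the
    tree's unpermuted OOB MSE; the per-tree increases are averaged and
    normalized by their standard error (raw mean if the spread is zero).
    IncNodePurity: total decrease in node sum-of-squares from splits on j,
    summed over the forest; a descriptor never used at any split scores 0.
    """
    n, p = model.X.shape
    rng = np.random.default_rng(model.seed + 1 if seed is None else seed)
    deltas = np.zeros((model.ntree, p))
    purity = np.zeros(p)
    used_any = np.zeros(p, dtype=bool)
    for t_i, (tree, idx) in enumerate(zip(model.trees, model.bootstrap_idx)):
        purity += _node_purity_decrease(tree, p)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if not oob.any():
            continue
        Xo, yo = model.X[oob], model.y[oob]
        base = np.mean((yo - tree.predict(Xo)) ** 2)
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        used_any[used] = True
        for j in used:      # unused features cannot change the prediction
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas[t_i, j] = np.mean((yo - tree.predict(Xp)) ** 2) - base
    mean_inc = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=0) / np.sqrt(model.ntree)
    pct_inc_mse = np.where(se > 0, mean_inc / np.where(se > 0, se, 1.0), mean_inc)
    names = model.descriptor_names or [f"X{j}" for j in range(p)]
    return pd.DataFrame({"descriptor": names, "pct_inc_mse": pct_inc_mse,
                         "inc_node_purity": purity}).set_index("descriptor")


@dataclass
class TuningResult:
    """Outcome of an mtry sweep or an ntree convergence experiment."""

    # mtry sweep: mtry value -> r2_oob over replications
    r2_oob: dict[int, list[float]] = field(default_factory=dict)
    # ntree curve: aligned lists
    tree_counts: list[int] = field(default_factory=list)
    mse_oob: list[float] = field(default_factory=list)
    mse_train: list[float] = field(default_factory=list)
    mse_test: list[float] = field(default_factory=list)

    def medians(self) -> dict[int, float]:
        return {m: float(np.nanmedian(v)) for m, v in self.r2_oob.items()}


def mtry_sweep(X: np.ndarray, y: np.ndarray, mtry_values: list[int],
               replications: int = 50, ntree: int = 100, seed: int = 0,
               min_node_size: int = 5) -> TuningResult:
    """Distribution of r2_oob over forest replications for each mtry value."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if replications < 2:
        raise ValueError("need at least 2 replications")
    for m in mtry_values:
        if not 1 <= m <= p:
            raise ValueError(f"mtry {m} outside [1, {p}]")
    rng = np.random.default_rng(seed)
    rep_seeds = [int(rng.integers(0, _SEED_MOD)) for _ in range(replications)]
    result = TuningResult()
    for m in mtry_values:
        vals = []
        for s in rep_seeds:
            model = fit_forest(X, y, ntree=ntree, mtry=m, seed=s ^ (m * 7919),
                               min_node_size=min_node_size)
            vals.append(oob_r2(model))
        result.r2_oob[m] = vals
    return result


def ntree_curve(X_train: np.ndarray, y_train: np.ndarray,
                X_test: np.ndarray, y_test: np.ndarray,
                tree_counts: list[int], seed: int = 0,
                mtry: int | None = None,
                min_node_size: int = 5) -> TuningResult:
    """OOB / train / test MSE as the forest grows.

    A single forest is fitted at ``max(tree_counts)`` and every prefix is
    evaluated, so the trajectory at the largest count coincides exactly with
    a directly fitted forest of that size and seed.
    """
    if not tree_counts:
        raise ValueError("tree_counts must be non-empty")
    counts = sorted(set(int(c) for c in tree_counts))
    model = fit_forest(X_train, y_train, ntree=counts[-1], mtry=mtry,
                       seed=seed, min_node_size=min_node_size)
    n = model.n_samples
    pred_tr = np.array([t.predict(model.X) for t in model.trees])
    pred_ts = np.array([t.predict(np.asarray(X_test, float))
                        for t in model.trees])
    oob_mask = np.ones((model.ntree, n), dtype=bool)
    for t_i, idx in enumerate(model.bootstrap_idx):
        oob_mask[t_i, idx] = False

    result = TuningResult(tree_counts=counts)
    cum_tr = np.cumsum(pred_tr, axis=0)
    cum_ts = np.cumsum(pred_ts, axis=0)
    cum_oob_sum = np.cumsum(pred_tr * oob_mask, axis=0)
    cum_oob_cnt = np.cumsum(oob_mask, axis=0)
    y_test = np.asarray(y_test, dtype=float)
    for c in counts:
        result.mse_train.append(
            float(np.mean((y_train - cum_tr[c - 1] / c) ** 2)))
        result.mse_test.append(
            float(np.mean((y_test - cum_ts[c - 1] / c) ** 2)))
        cnt = cum_oob_cnt[c - 1]
        has = cnt > 0
        oob_pred = cum_oob_sum[c - 1][has] / cnt[has]
        result.mse_oob.append(
            float(np.mean((y_train[has] - oob_pred) ** 2)))
    return result
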