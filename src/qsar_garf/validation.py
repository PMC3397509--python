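"""Internal and external validation statistics for QSAR regression models.

The battery follows the Golbraikh-Tropsha and Roy conventions:

* ``r2_ncv`` / ``r2_ts`` -- squared Pearson correlation between observed and
  predicted values (training resp. test set);
* ``r2_cv`` -- PRESS-based cross-validated coefficient on the training set,
  1 - sum((y - yhat)^2) / sum((y - ybar_tr)^2), computed here from out-of-bag
  predictions;
* ``r2_pred`` -- the external analogue: PRESS over the test set divided by
  SD, the squared deviations of test observations from the *training* mean;
* ``k`` and ``r2_o`` -- slope and determination coefficient of the
  least-squares line through the origin, observed regressed on predicted
  (k = sum(y*yhat)/sum(yhat^2); the r2_o denominator uses deviations from
  the test-set observed mean);
* ``r2_m`` -- Roy's modified metric r2_ts * (1 - sqrt(r2_ts - r2_o)),
  penalizing divergence between the with- and without-intercept fits;
* the Tropsha acceptability gate: r2_pred > 0.5, r2_ts > 0.6,
  (r2_ts - r2_o)/r2_ts < 0.1 and 0.85 <= k <= 1.15 (strict inequalities as
  stated);
* Y-randomization: the training activities are shuffled, the full modelling
  procedure refitted, and the battery recomputed -- a real model's
  statistics must collapse under this null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .datasets import QSARDataset

__all__ = ["PredictionSet", "ValidationReport", "YRandResult", "rmse",
           "r2_pearson", "r2_press", "r2_pred", "origin_stats", "r2_m",
           "tropsha_check", "full_report", "report_from_fixture",
           "y_randomization"]

_SEED_MOD = 2**31 - 1


@dataclass
class PredictionSet:
    """Observed/predicted pairs plus the training-mean reference.

    ``reference_mean`` is the training-set observed mean (ybar_tr) used by
    the PRESS-based denominators; it defaults to the mean of ``y`` itself,
    which is correct for training-set statistics.
    """

    y: np.ndarray
    yhat: np.ndarray
    reference_mean: Optional[float] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.yhat = np.asarray(self.yhat, dtype=float)
        if self.y.shape != self.yhat.shape or self.y.ndim != 1:
            raise ValueError("y and yhat must be 1-D arrays of equal length")
        if self.y.size < 2:
            raise ValueError("need at least 2 observations")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.yhat))):
            raise ValueError("observations and predictions must be finite")
        if self.reference_mean is None:
            self.reference_mean = float(self.y.mean())


def rmse(ps: PredictionSet) -> float:
    """Root mean squared residual, sqrt(sum((y - yhat)^2) / n)."""
    return float(np.sqrt(np.mean((ps.y - ps.yhat) ** 2)))


def r2_pearson(ps: PredictionSet) -> float:
    """Squared Pearson correlation; NaN when either vector is constant."""
    if ps.y.std() == 0.0 or ps.yhat.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(ps.y, ps.yhat)[0, 1] ** 2)


def r2_press(ps: PredictionSet) -> float:
    """PRESS-based coefficient 1 - sum((y-yhat)^2) / sum((y-ybar_ref)^2).

    With out-of-bag (or cross-validated) predictions on the training set
    this is r2_cv; it may be negative for worse-than-mean predictions.
    """
    denom = float(np.sum((ps.y - ps.reference_mean) ** 2))
    if denom == 0.0:
        raise ValueError("zero denominator: observations equal the reference mean")
    return 1.0 - float(np.sum((ps.y - ps.yhat) ** 2)) / denom


def r2_pred(test_ps: PredictionSet) -> float:
    """External predictive coefficient 1 - PRESS/SD over the test set.

    ``test_ps.reference_mean`` must be the training-set observed mean.
    """
    return r2_press(test_ps)


def origin_stats(test_ps: PredictionSet) -> tuple[float, float]:
    """Slope and determination coefficient of the through-origin fit.

    Observed is regressed on predicted with zero intercept:
    k = sum(y * yhat) / sum(yhat^2), and
    r2_o = 1 - sum((y - k*yhat)^2) / sum((y - mean(y))^2).
    """
    denom = float(np.sum(test_ps.yhat ** 2))
    if denom == 0.0:
        raise ValueError("all-zero predictions: through-origin slope undefined")
    k = float(np.sum(test_ps.y * test_ps.yhat)) / denom
    ss_res = float(np.sum((test_ps.y - k * test_ps.yhat) ** 2))
    ss_tot = float(np.sum((test_ps.y - test_ps.y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant observations: r2_o undefined")
    return k, 1.0 - ss_res / ss_tot


def r2_m(r2_ts: float, r2_o: float) -> float:
    """Roy's modified metric r2_ts * (1 - sqrt(r2_ts - r2_o)).

    Equals r2_ts when the through-origin fit matches the free fit, and
    approaches 0 as they diverge. A (numerically) negative difference is
    clamped to zero with a warning.
    """
    diff = r2_ts - r2_o
    if diff < -1e-9:
        warnings.warn(f"r2_o ({r2_o:.4f}) exceeds r2_ts ({r2_ts:.4f}); "
                      "clamping the difference at 0", stacklevel=2)
    diff = max(diff, 0.0)
    return float(r2_ts * (1.0 - np.sqrt(diff)))


@dataclass
class ValidationReport:
    """The full statistic set with Tropsha pass/fail flags."""

    r2_ncv: float
    r2_cv: float
    rmse_train: float
    r2_ts: float
    r2_pred: float
    rmse_test: float
    r2_o: float
    k: float
    r2_m: float
    delta: float                 # (r2_ts - r2_o) / r2_ts
    press: float
    sd: float
    n_train: int
    n_test: int
    tropsha_flags: dict[str, bool] = field(default_factory=dict)
    tropsha_pass: bool = False

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()
               if k not in ("tropsha_flags",)}
        for name, ok in self.tropsha_flags.items():
            out[f"tropsha_{name}"] = ok
        return out

    def summary(self) -> str:
        lines = [
            "QSAR validation report",
            "=" * 46,
            f"training set (n = {self.n_train})",
            f"  r2_ncv       {self.r2_ncv:8.4f}",
            f"  r2_cv        {self.r2_cv:8.4f}",
            f"  RMSE         {self.rmse_train:8.4f}",
            f"test set (n = {self.n_test})",
            f"  r2_ts        {self.r2_ts:8.4f}",
            f"  r2_pred      {self.r2_pred:8.4f}",
            f"  RMSE         {self.rmse_test:8.4f}",
            f"  k            {self.k:8.4f}",
            f"  r2_o         {self.r2_o:8.4f}",
            f"  r2_m         {self.r2_m:8.4f}",
            f"  (r2_ts-r2_o)/r2_ts {self.delta:8.4f}",
            "Tropsha criteria: "
            + ("PASS" if self.tropsha_pass else "FAIL")
            + "  (" + ", ".join(f"{n}={'ok' if v else 'fail'}"
                                for n, v in self.tropsha_flags.items()) + ")",
        ]
        return "\n".join(lines)


def tropsha_check(report: ValidationReport) -> tuple[dict[str, bool], bool]:
    """Evaluate the acceptability criteria with strict inequalities."""
    flags = {
        "r2_pred_gt_0.5": report.r2_pred > 0.5,
        "r2_ts_gt_0.6": report.r2_ts > 0.6,
        "delta_lt_0.1": report.delta < 0.1,
        "k_in_0.85_1.15": 0.85 <= report.k <= 1.15,
    }
    return flags, all(flags.values())


def full_report(train_ps: PredictionSet,
                oob_ps: Optional[PredictionSet],
                test_ps: PredictionSet) -> ValidationReport:
    """Assemble the complete battery from training, OOB and test predictions.

    ``oob_ps`` may be None when no cross-validated predictions exist (e.g.
    when scoring externally supplied prediction columns); r2_cv is then NaN.
    """
    ktest, r2o = origin_stats(test_ps)
    r2ts = r2_pearson(test_ps)
    press = float(np.sum((test_ps.y - test_ps.yhat) ** 2))
    sd = float(np.sum((test_ps.y - test_ps.reference_mean) ** 2))
    report = ValidationReport(
        r2_ncv=r2_pearson(train_ps),
        r2_cv=r2_press(oob_ps) if oob_ps is not None else float("nan"),
        rmse_train=rmse(train_ps),
        r2_ts=r2ts,
        r2_pred=r2_pred(test_ps),
        rmse_test=rmse(test_ps),
        r2_o=r2o,
        k=ktest,
        r2_m=r2_m(r2ts, r2o),
        delta=(r2ts - r2o) / r2ts,
        press=press,
        sd=sd,
        n_train=train_ps.y.size,
        n_test=test_ps.y.size,
    )
    report.tropsha_flags, report.tropsha_pass = tropsha_check(report)
    return report


def report_from_fixture(model: str = "garf") -> ValidationReport:
    """Recompute the validation battery from the packaged benchmark table."""
    from .datasets import fixture_dataset
    y, yhat, is_test = fixture_dataset(model)
    ybar_tr = float(y[~is_test].mean())
    train_ps = PredictionSet(y[~is_test], yhat[~is_test], ybar_tr)
    test_ps = PredictionSet(y[is_test], yhat[is_test], ybar_tr)
    return full_report(train_ps, None, test_ps)


# A fitting procedure maps (X_train, y_train, X_test, seed) to
# (yhat_train, yhat_oob_or_None, yhat_test).
FitProcedure = Callable[[np.ndarray, np.ndarray, np.ndarray, int],
                        tuple[np.ndarray, Optional[np.ndarray], np.ndarray]]


@dataclass
class YRandResult:
    """Per-round and averaged statistics of the Y-randomization check."""

    rounds: int
    seed: int
    reports: list[ValidationReport]

    def mean_statistics(self) -> dict[str, float]:
        keys = ["r2_ncv", "r2_cv", "r2_ts", "r2_pred", "r2_m",
                "rmse_train", "rmse_test"]
        return {k: float(np.nanmean([getattr(r, k) for r in self.reports]))
                for k in keys}


def y_randomization(dataset: QSARDataset, procedure: FitProcedure,
                    rounds: int = 500, seed: int = 0,
                    shuffle: bool = True) -> YRandResult:
    """Refit the modelling procedure on label-permuted training activities.

    Per round, the training activities are shuffled with a round-specific
    seed (``shuffle=False`` forces the identity permutation, a consistency
    hook), the procedure refitted, and a full report computed: training
    statistics against the permuted labels, test statistics against the true
    test activities.
    """
    if rounds < 1:
        raise ValueError("rounds must be at least 1")
    X_train, y_train = dataset.training_xy()
    X_test, y_test = dataset.test_xy()
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(rounds):
        round_seed = int(rng.integers(0, _SEED_MOD))
        y_perm = (np.random.default_rng(round_seed).permutation(y_train)
                  if shuffle else y_train.copy())
        yhat_tr, yhat_oob, yhat_ts = procedure(X_train, y_perm, X_test,
                                               round_seed)
        ybar = float(y_perm.mean())
        train_ps = PredictionSet(y_perm, yhat_tr, ybar)
        oob_ps = (PredictionSet(y_perm, yhat_oob, ybar)
                  if yhat_oob is not None else None)
        test_ps = PredictionSet(y_test, yhat_ts, ybar)
        reports.append(full_report(train_ps, oob_ps, test_ps))
    return YRandResult(rounds=rounds, seed=seed, reports=reports)
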