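"""The GA-RF model object: preprocessing, splitting, selection, validation.

Usage follows the model/results convention::

    model = GARF(dataset, config)          # or GARF.from_csv(...)
    results = model.fit()
    print(results.summary())

``fit`` runs the full pipeline: descriptor filters -> SOM train/test split
(skipped when the dataset already carries one) -> GA descriptor selection
with RF OOB-MSE fitness -> final forest on the selected descriptors (mtry =
floor(p_selected / 3) unless overridden) -> the complete validation battery.
All stages draw their seeds from the config, so a refit is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .datasets import (QSARDataset, UNASSIGNED, assemble_dataset,
                       read_activity_csv, read_descriptor_csv)
from .forest import ForestModel, default_mtry, fit_forest, variable_importance
from .ga import GAResult, run_ga
from .preprocess import FilterReport, preprocess_pipeline
from .som import SplitAssignment, map_to_bmu, split_by_som, train_som
from .validation import (PredictionSet, ValidationReport, YRandResult,
                         full_report, y_randomization)

__all__ = ["GARF", "GARFResults", "RunManifest"]


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    timestamp: str
    config: dict
    input_digests: dict[str, str]
    stage_outputs: dict[str, object]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class GARF:
    """GA-RF QSAR model over a descriptor matrix and pIC50 activities."""

    def __init__(self, dataset: QSARDataset,
                 config: PipelineConfig | None = None):
        self.dataset = dataset
        self.config = config or PipelineConfig()
        self._input_digests: dict[str, str] = {}

    @classmethod
    def from_csv(cls, matrix_path: str | Path, activity_path: str | Path,
                 config: PipelineConfig | None = None) -> "GARF":
        matrix = read_descriptor_csv(matrix_path)
        activity = read_activity_csv(activity_path)
        model = cls(assemble_dataset(matrix, activity), config)
        model._input_digests = {str(matrix_path): _digest(matrix_path),
                                str(activity_path): _digest(activity_path)}
        return model

    def fit(self, select: bool = True) -> "GARFResults":
        """Run the pipeline; ``select=False`` skips the GA (pure-RF model)."""
        cfg = self.config
        stage: dict[str, object] = {}

        filtered, report = preprocess_pipeline(self.dataset.matrix, cfg)
        stage["descriptors_in"] = self.dataset.matrix.n_descriptors
        stage["descriptors_filtered"] = filtered.n_descriptors

        data = QSARDataset(filtered, self.dataset.activity,
                           list(self.dataset.split))
        split = None
        if all(s == UNASSIGNED for s in data.split):
            n = data.matrix.n_compounds
            test_size = cfg.test_size or max(1, round(n / 3))
            grid = train_som(data.matrix, cfg.som_iterations, cfg.seed,
                             cfg.som_rows, cfg.som_cols)
            bmu = map_to_bmu(grid, data.matrix)
            split = split_by_som(data.matrix, bmu, test_size, cfg.seed)
            data = data.with_split(split.label)
        stage["n_train"] = int(data.train_mask.sum())
        stage["n_test"] = int(data.test_mask.sum())

        ga_result = None
        selected = list(data.matrix.descriptor_names)
        if select:
            ga_result = run_ga(data, cfg.ga)
            selected = ga_result.selected_descriptors
        stage["descriptors_selected"] = len(selected)

        model_data = QSARDataset(data.matrix.select_descriptors(selected),
                                 data.activity, list(data.split))
        X_tr, y_tr = model_data.training_xy()
        X_ts, y_ts = model_data.test_xy()
        mtry = cfg.rf_mtry or default_mtry(len(selected))
        forest = fit_forest(X_tr, y_tr, ntree=cfg.rf_ntree, mtry=mtry,
                            seed=cfg.seed,
                            min_node_size=cfg.rf_min_node_size,
                            descriptor_names=selected)

        ybar_tr = float(y_tr.mean())
        train_ps = PredictionSet(y_tr, forest.predict(X_tr), ybar_tr)
        oob_ps = (PredictionSet(y_tr, forest.oob_prediction, ybar_tr)
                  if not forest.oob_missing.any() else None)
        test_ps = PredictionSet(y_ts, forest.predict(X_ts), ybar_tr)
        report_v = full_report(train_ps, oob_ps, test_ps)

        manifest = RunManifest(
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            config=cfg.to_dict(),
            input_digests=dict(self._input_digests),
            stage_outputs=stage,
        )
        return GARFResults(model=self, data=model_data,
                           filter_report=report, split=split,
                           ga_result=ga_result, forest=forest,
                           report=report_v, manifest=manifest)


@dataclass
class GARFResults:
    """Fitted GA-RF pipeline: selection, forest, statistics, provenance."""

    model: GARF
    data: QSARDataset
    filter_report: FilterReport
    split: Optional[SplitAssignment]
    ga_result: Optional[GAResult]
    forest: ForestModel
    report: ValidationReport
    manifest: RunManifest

    @property
    def selected_descriptors(self) -> list[str]:
        return list(self.data.matrix.descriptor_names)

    def importance(self) -> pd.DataFrame:
        return variable_importance(self.forest)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(X)

    def y_randomize(self, rounds: int | None = None,
                    seed: int | None = None) -> YRandResult:
        """Y-randomization of the final forest on the selected descriptors."""
        cfg = self.model.config

        def procedure(X_tr, y_tr, X_ts, round_seed):
            f = fit_forest(X_tr, y_tr, ntree=cfg.rf_ntree,
                           mtry=self.forest.mtry, seed=round_seed,
                           min_node_size=cfg.rf_min_node_size)
            return f.predict(X_tr), f.oob_prediction, f.predict(X_ts)

        return y_randomization(self.data, procedure,
                               rounds=rounds or cfg.yrand_rounds,
                               seed=cfg.seed if seed is None else seed)

    def summary(self) -> str:
        st = self.manifest.stage_outputs
        head = [
            "GA-RF QSAR model",
            "=" * 46,
            f"descriptors: {st['descriptors_in']} -> "
            f"{st['descriptors_filtered']} (filtered) -> "
            f"{st['descriptors_selected']} (selected)",
            f"compounds:   {st['n_train']} train / {st['n_test']} test",
            f"forest:      ntree = {self.forest.ntree}, "
            f"mtry = {self.forest.mtry}",
        ]
        if self.ga_result is not None:
            head.append(f"GA: best OOB MSE = {self.ga_result.best_fitness:.4f}"
                        f" after {self.ga_result.evaluations} evaluations "
                        f"(cache hit rate {self.ga_result.cache_hit_rate:.2f})")
        return "\n".join(head) + "\n\n" + self.report.summary()
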