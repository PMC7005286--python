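"""Repeated censoring-stratified cross-validation and score aggregation.

The protocol: k-fold splits that preserve the cohort's censored fraction,
repeated over several iterations with fresh shuffles; all preprocessing
(imputation statistics, encoding statistics, the time-bin grid) is fitted
on each fold's training portion only.  The headline score of a model is the
mean over iterations of its per-iteration fold-mean, reported as
mean +/- SD across iterations.  An external cohort, when supplied, is scored
by every fold-trained model the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalData, stratified_folds
from .metrics import auc_3yr, concordance_index, predicted_duration
from .models import CoxPHBaseline, ModelConfig, make_model

__all__ = ["CVSpec", "ScoreTable", "run_cv", "aggregate", "cv_mean_cindex"]


@dataclass(frozen=True)
class CVSpec:
    """Repeated stratified cross-validation layout.

    Iteration ``i`` shuffles folds with seed ``base_seed + i``; model
    training inside iteration ``i``, fold ``f`` uses seed
    ``base_seed + 1000*i + f`` so that re-running with the same base seed
    reproduces every cell.
    """

    n_folds: int = 5
    n_iterations: int = 10
    base_seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")

    def fold_seed(self, iteration: int) -> int:
        return self.base_seed + iteration

    def fit_seed(self, iteration: int, fold: int) -> int:
        return self.base_seed + 1000 * iteration + fold


@dataclass
class ScoreTable:
    """Tidy per-cell scores: one row per (model, iteration, fold, cohort, metric)."""

    cells: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SD per model/cohort/metric over iteration-level means."""
        return aggregate(self)

    def iteration_means(self) -> pd.DataFrame:
        ok = self.cells.dropna(subset=["value"])
        return (
            ok.groupby(["model", "cohort", "metric", "iteration"], as_index=False)["value"]
            .mean()
        )

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _score_cells(pred_durations, cohort: SurvivalData):
    """C-index and 3-year AUC of predicted durations on one cohort."""
    out = {}
    try:
        out["c_index"] = (concordance_index(pred_durations, cohort.durations, cohort.events), "")
    except ValueError as exc:
        out["c_index"] = (float("nan"), str(exc))
    try:
        auc, _ = auc_3yr(pred_durations, cohort.durations, cohort.events)
        out["auc"] = (auc, "")
    except ValueError as exc:
        out["auc"] = (float("nan"), str(exc))
    return out


def _predict_duration(fitted, cohort: SurvivalData) -> np.ndarray:
    # BTSResults: hazard-weighted bin midpoints; CoxResults: expected survival time
    return fitted.predicted_duration(cohort)


def run_cv(ds: SurvivalData, models: dict, spec: CVSpec,
           external: SurvivalData | None = None) -> ScoreTable:
    """Run the repeated stratified CV protocol for several model configs.

    ``models`` maps a display name to a :class:`~binsurv.models.ModelConfig`.
    Fold-level fit failures are recorded as missing cells with the reason,
    never raised.
    """
    rows = []
    for iteration in range(spec.n_iterations):
        folds = stratified_folds(ds, spec.n_folds, seed=spec.fold_seed(iteration))
        all_idx = np.arange(len(ds))
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            train, test = ds.subset(train_idx), ds.subset(test_idx)
            for name, config in models.items():
                cohorts = {"test": test}
                if external is not None:
                    cohorts["external"] = external
                try:
                    fitted = _fit_one(config, train, seed=spec.fit_seed(iteration, fold_id))
                except Exception as exc:  # recorded, not raised
                    for cohort_name in cohorts:
                        for metric in ("c_index", "auc"):
                            rows.append((name, iteration, fold_id, cohort_name, metric,
                                         float("nan"), f"fit failed: {exc}"))
                    continue
                for cohort_name, cohort in cohorts.items():
                    pred = _predict_duration(fitted, cohort)
                    for metric, (value, reason) in _score_cells(pred, cohort).items():
                        rows.append((name, iteration, fold_id, cohort_name, metric,
                                     value, reason))
    cells = pd.DataFrame(
        rows, columns=["model", "iteration", "fold", "cohort", "metric", "value", "note"]
    )
    return ScoreTable(cells)


def _fit_one(config: ModelConfig, train: SurvivalData, seed: int):
    from dataclasses import replace

    model = make_model(replace(config, seed=seed) if config.kind != "cox" else config, train)
    if isinstance(model, CoxPHBaseline):
        return model.fit()
    return model.fit()


def aggregate(table: ScoreTable) -> pd.DataFrame:
    """Two-level aggregation: fold-mean per iteration, then mean +/- SD."""
    iter_means = table.iteration_means()
    grouped = iter_means.groupby(["model", "cohort", "metric"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                      n_iterations="count").reset_index()
    return out


def cv_mean_cindex(ds: SurvivalData, config: ModelConfig, spec: CVSpec,
                   features: list | None = None) -> float:
    """Mean cross-validated C-index of one model, optionally on a feature subset."""
    data = ds if features is None else ds.select_features(features)
    table = run_cv(data, {"m": config}, spec)
    cells = table.cells
    mask = (cells["metric"] == "c_index") & (cells["cohort"] == "test")
    return float(cells.loc[mask, "value"].mean())
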