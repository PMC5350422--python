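"""Validation metrics for fingerprint-activity models.

The reporting convention followed here is the chemometric standard:

* RMSET / RMSECV / RMSEP — root-mean-squared error of the training fit,
  of leave-one-out cross-validation, and of external test-set prediction;
* R2 (training and test) — squared Pearson correlation between predicted
  and experimental activities;
* q2 = 1 - sum(y_pred - y_act)^2 / sum(y_act - mean(y_act))^2 — the
  cross-validated determination coefficient (q2 and test R2 generally
  differ: R2 is insensitive to bias and scale, q2 is not);
* per-sample REP / PRESS — the prediction error of each test sample and
  its square.  REP is reported as the plain difference predicted - actual
  (the convention the reference tables actually follow); a relative
  (ratio-to-actual) variant is available behind ``relative=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ValidationReport", "rep_press", "rmse", "r2_corr", "q2",
           "validation_report", "batch_summary", "load_table1", "load_table3"]


def _pair(actual, predicted):
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(a) != len(p):
        raise ValueError(f"length mismatch: {len(a)} actual vs {len(p)} predicted")
    return a, p


def rep_press(actual, predicted, relative: bool = False):
    """Per-sample prediction error and its square.

    ``rep_i = predicted_i - actual_i`` (or the ratio to ``actual_i`` with
    ``relative=True``); ``press_i = rep_i ** 2``.
    """
    a, p = _pair(actual, predicted)
    rep = (p - a) / a if relative else p - a
    return rep, rep ** 2


def rmse(actual, predicted) -> float:
    """Root mean squared error sqrt(mean((predicted - actual)^2))."""
    a, p = _pair(actual, predicted)
    if len(a) == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def r2_corr(actual, predicted) -> float:
    """Squared Pearson correlation of predicted vs experimental values."""
    a, p = _pair(actual, predicted)
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("degenerate input: zero variance")
    return float(np.corrcoef(a, p)[0, 1] ** 2)


def q2(actual, predicted) -> float:
    """Cross-validated determination coefficient (can be negative)."""
    a, p = _pair(actual, predicted)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("degenerate input: actual values have zero variance")
    return 1.0 - float(np.sum((p - a) ** 2)) / ss_tot


@dataclass
class ValidationReport:
    """Training + test metric set for one fitted model."""

    model_name: str
    n_components: int
    n_variables: int
    r2_train: float
    rmset: float
    rmsecv: float | None
    r2_test: float
    rmsep: float
    q2_test: float
    per_sample: pd.DataFrame  # columns: sample_id, actual, predicted, rep, press

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("model_name", "n_components", "n_variables", "r2_train",
              "rmset", "rmsecv", "r2_test", "rmsep", "q2_test")}
        d["per_sample"] = self.per_sample.to_dict(orient="records")
        return d


def validation_report(model, X_train, y_train, X_test, y_test,
                      rmsecv: float | None = None, model_name: str = "PLS",
                      test_ids=None) -> ValidationReport:
    """Assemble the full metric set for a fitted model.

    ``model`` must expose ``predict`` on full-grid matrices plus the fitted
    attributes ``n_components_`` (or a ``pls_`` holding them) and a
    coefficient vector; both the plain PLS and the EN-PLS estimators
    qualify.
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    fit_pred = model.predict(X_train)
    test_pred = model.predict(X_test)
    rep, press = rep_press(y_test, test_pred)
    ids = list(test_ids) if test_ids is not None else list(range(1, len(y_test) + 1))
    per_sample = pd.DataFrame({"sample_id": ids, "actual": y_test,
                               "predicted": test_pred, "rep": rep, "press": press})
    core = getattr(model, "pls_", model)
    return ValidationReport(
        model_name=model_name,
        n_components=int(core.n_components_),
        n_variables=int(len(core.coef_)),
        r2_train=r2_corr(y_train, fit_pred),
        rmset=rmse(y_train, fit_pred),
        rmsecv=None if rmsecv is None else float(rmsecv),
        r2_test=r2_corr(y_test, test_pred),
        rmsep=rmse(y_test, test_pred),
        q2_test=q2(y_test, test_pred),
        per_sample=per_sample)


def batch_summary(activities: pd.DataFrame, value_col: str = "activity",
                  batch_col: str = "batch") -> pd.DataFrame:
    """Mean / sample SD / min / max of activity per batch.

    SD uses the n-1 (sample) convention.  Input is a tidy frame with one
    row per sample.
    """
    g = activities.groupby(batch_col)[value_col]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1),
                        "min": g.min(), "max": g.max(), "n": g.size()})
    return out


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("qpar.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Packaged reference panel: 72 CD80 activities (delta % scale) in 3 batches."""
    return _load_csv("table1_activities.csv")


def load_table3() -> pd.DataFrame:
    """Packaged reference test-set table: 24 actual activities (100+delta
    scale) with PLS and EN-PLS predictions and their printed REP/PRESS."""
    return _load_csv("table3_testset.csv")
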