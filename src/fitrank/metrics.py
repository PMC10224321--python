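"""Confusion-matrix criteria, regression metrics, and linear feature ranking.

The six classification criteria used throughout ranking are F1, FPR, TPR,
precision, NPV, and FDR, always carried alongside the raw confusion counts.
Ratios with zero denominators are reported as ``None`` and flagged in
``MetricReport.undefined`` rather than silently coerced; F1 follows the
convention of being 0 when precision + recall is zero or undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConstantTargetError, FitrankError

__all__ = [
    "MetricReport",
    "RegressionReport",
    "classification_metrics",
    "f1_from_precision_recall",
    "regression_metrics",
    "rank_features",
    "CRITERIA",
]

#: Fixed criterion order used by decision matrices downstream.
CRITERIA = ("F1", "FPR", "TPR", "precision", "NPV", "FDR")


@dataclass(frozen=True)
class MetricReport:
    tp: int
    fp: int
    fn: int
    tn: int
    f1: float
    precision: float | None
    tpr: float | None
    fpr: float | None
    npv: float | None
    fdr: float | None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "F1": self.f1,
            "FPR": self.fpr,
            "TPR": self.tpr,
            "precision": self.precision,
            "NPV": self.npv,
            "FDR": self.fdr,
        }


@dataclass(frozen=True)
class RegressionReport:
    mse: float
    r2: float

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise FitrankError("MSE cannot be negative")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _ratio(numerator: int, denominator: int) -> float | None:
    return numerator / denominator if denominator > 0 else None


def classification_metrics(true_labels, predicted_labels) -> MetricReport:
    """Compute the six criteria and confusion counts for binary predictions."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if len(y_true) != len(y_pred):
        raise FitrankError(
            f"label vectors differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    if len(y_true) == 0:
        raise FitrankError("cannot compute metrics on an empty test set")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        if not np.isin(arr, (0, 1)).all():
            raise FitrankError(f"{name} labels must be binary 0/1")

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))

    precision = _ratio(tp, tp + fp)
    tpr = _ratio(tp, tp + fn)
    fpr = _ratio(fp, fp + tn)
    npv = _ratio(tn, tn + fn)
    fdr = 1.0 - precision if precision is not None else None

    undefined = frozenset(
        name
        for name, value in (
            ("precision", precision),
            ("TPR", tpr),
            ("FPR", fpr),
            ("NPV", npv),
            ("FDR", fdr),
        )
        if value is None
    )
    if precision is None or tpr is None:
        f1 = 0.0
    else:
        f1 = f1_from_precision_recall(precision, tpr)

    return MetricReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        f1=f1, precision=precision, tpr=tpr, fpr=fpr, npv=npv, fdr=fdr,
        undefined=undefined,
    )


def regression_metrics(true_values, predicted_values) -> RegressionReport:
    """MSE and R^2 = 1 - SS_res / SS_tot.

    A constant target makes R^2 undefined: a :class:`ConstantTargetError` is
    raised carrying the computed ``.mse``.
    """
    y = np.asarray(true_values, dtype=float)
    y_hat = np.asarray(predicted_values, dtype=float)
    if len(y) != len(y_hat):
        raise FitrankError(f"value vectors differ in length: {len(y)} vs {len(y_hat)}")
    if len(y) < 2:
        raise FitrankError("regression metrics need at least 2 observations")
    mse = float(np.mean((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConstantTargetError(
            "R^2 is undefined for a constant target", mse=mse
        )
    ss_res = float(np.sum((y - y_hat) ** 2))
    return RegressionReport(mse=mse, r2=1.0 - ss_res / ss_tot)


def rank_features(model_handle, feature_names) -> list[tuple[str, float]]:
    """Rank features of a fitted linear model by absolute standardized coefficient.

    Descending, with stable input-order tie-breaking. Warns when the handle
    was fitted without standardization (importances not comparable).
    """
    feature_names = list(feature_names)
    coefficients = np.asarray(model_handle.coefficients, dtype=float).ravel()
    if len(coefficients) != len(feature_names):
        raise FitrankError(
            f"model has {len(coefficients)} coefficients but "
            f"{len(feature_names)} feature names were given"
        )
    if not getattr(model_handle, "standardized", False):
        warnings.warn(
            "model was fitted without standardization; "
            "coefficient magnitudes are not comparable across features",
            stacklevel=2,
        )
    importance = np.abs(coefficients)
    order = np.argsort(-importance, kind="stable")
    return [(feature_names[i], float(importance[i])) for i in order]
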