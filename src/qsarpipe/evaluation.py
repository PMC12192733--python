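"""Classification/regression performance metrics and the external
cross-validation harness.

Metrics are computed from explicit confusion counts. A metric whose
denominator is zero is reported as *undefined* (``None``), never as a
silent zero, so fold aggregation cannot average fabricated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Binary-classification metrics; ``None`` marks an undefined value."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    specificity: float | None
    fpr: float | None
    fnr: float | None
    mcc: float | None
    f1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, recall, precision, specificity, FPR, FNR, MCC and F1
    from confusion counts.

    MCC uses the four-factor denominator
    sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)); if any factor is zero the MCC is
    undefined.
    """
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    accuracy = _ratio(tp + tn, counts.total)
    recall = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    specificity = _ratio(tn, tn + fp)
    # complements computed as such so fpr == 1 - specificity exactly
    fpr = None if specificity is None else 1.0 - specificity
    fnr = None if recall is None else 1.0 - recall

    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None

    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)

    return MetricsReport(
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        specificity=specificity,
        fpr=fpr,
        fnr=fnr,
        mcc=mcc,
        f1=f1,
    )


def confusion_from_labels(
    y_true: Sequence, y_pred: Sequence, positive=1
) -> ConfusionCounts:
    """Count TP/TN/FP/FN treating ``positive`` as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t == positive:
            fn += 1
        elif p == positive:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot; may be negative."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2 or y.size != yhat.size:
        raise ValueError("need two aligned vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class CVReport:
    """Per-fold metric reports plus mean +/- sd aggregates.

    Aggregation skips undefined (None) fold values and records how many
    folds contributed to each aggregate.
    """

    folds: list[MetricsReport]

    def aggregate(self) -> dict[str, dict[str, float | int | None]]:
        out: dict[str, dict[str, float | int | None]] = {}
        names = [f.name for f in fields(MetricsReport)]
        for name in names:
            values = [getattr(r, name) for r in self.folds]
            defined = [v for v in values if v is not None]
            if defined:
                out[name] = {
                    "mean": float(np.mean(defined)),
                    "sd": float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0,
                    "n_folds": len(defined),
                }
            else:
                out[name] = {"mean": None, "sd": None, "n_folds": 0}
        return out


def external_cv(
    builder: Callable,
    X: np.ndarray,
    y: Sequence,
    folds: int = 10,
    seed: int = 0,
    positive=1,
) -> CVReport:
    """Stratified k-fold external evaluation.

    ``builder(X_train, y_train)`` must return a fitted object with a
    ``predict`` method. The data are partitioned once; the builder is
    retrained per fold on the complement and scored on the held-out
    fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise ValueError("stratification error: each class needs >= folds members")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in splitter.split(X, y):
        model = builder(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        counts_ = confusion_from_labels(y[test_idx], pred, positive=positive)
        reports.append(classification_metrics(counts_))
    return CVReport(folds=reports)


def cv_report_to_frame(report: CVReport):
    """CSV-friendly layout: one row per fold plus a mean +/- sd row."""
    import pandas as pd

    rows = [r.as_dict() for r in report.folds]
    df = pd.DataFrame(rows)
    df.index = [f"fold_{i+1}" for i in range(len(rows))]
    agg = report.aggregate()
    df.loc["mean"] = {k: v["mean"] for k, v in agg.items()}
    df.loc["sd"] = {k: v["sd"] for k, v in agg.items()}
    return df
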