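"""Cross-validated evaluation with the five confusion-matrix metrics.

Metrics (all from TP/TN/FP/FN of the positive class, or one-vs-rest per
class for multiclass data):

    ACC = (TP + TN) / (TP + FP + TN + FN)
    RE  = TP / (TP + FN)
    PE  = TP / (TP + FP)
    F   = 2 * PE * RE / (PE + RE)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

Zero-denominator conventions: PE = 0 when TP + FP = 0; RE = 0 when
TP + FN = 0; F = 0 when PE + RE = 0; MCC = 0 when any denominator factor is
0. A class never predicted therefore reports PE = RE = F = 0 rather than
NaN, which is what happens to very small classes in practice.

Cross-validation is stratified 5-fold with a seeded shuffle. When a feature
selector is configured it is refitted on each fold's training split only
(leakage-safe); ``paper_mode=True`` instead selects once on the full matrix
before splitting. Fold metrics are aggregated by arithmetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.linear_model import SGDClassifier

from .features import DEFAULT_ALPHA, FeatureMatrix, encode_dataset
from .sequence_io import ProteinRecord

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ClassifierSpec",
    "CVReport",
    "confusion",
    "metric_set",
    "multiclass_report",
    "cross_validate",
    "alpha_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    recall: float
    precision: float
    f_measure: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
        }


def confusion(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionCounts:
    """Exact TP/TN/FP/FN counts for one positive-class definition."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    seen = set(np.unique(yt).tolist())
    unseen = [v for v in np.unique(yp).tolist() if v not in seen]
    if unseen:
        raise ValueError(f"predicted label(s) never present in y_true: {unseen}")
    tp = int(np.sum((yt == positive) & (yp == positive)))
    tn = int(np.sum((yt != positive) & (yp != positive)))
    fp = int(np.sum((yt != positive) & (yp == positive)))
    fn = int(np.sum((yt == positive) & (yp != positive)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metric_set(c: ConfusionCounts) -> MetricSet:
    """The five metrics from one confusion table, with the zero conventions."""
    if c.total <= 0:
        raise ValueError("confusion table must count at least one sample")
    acc = (c.tp + c.tn) / c.total
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    f_measure = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    denom = (
        (c.tp + c.fp) * (c.tn + c.fn) * (c.tp + c.fn) * (c.tn + c.fp)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom > 0 else 0.0
    )
    return MetricSet(acc=acc, recall=recall, precision=precision,
                     f_measure=f_measure, mcc=mcc)


@dataclass
class MulticlassReport:
    per_class: dict[Any, MetricSet]
    acc: float
    mcc: float


def multiclass_report(
    y_true: Sequence, y_pred: Sequence, mcc_mode: str = "multiclass"
) -> MulticlassReport:
    """Per-class one-vs-rest metrics plus overall accuracy and MCC.

    The overall MCC is the generalized multiclass correlation computed from
    the full confusion matrix (``mcc_mode="multiclass"``, reducing exactly to
    the binary MCC for two classes); ``mcc_mode="macro"`` instead averages
    the per-class one-vs-rest MCCs.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    classes = np.unique(yt)
    if classes.size < 2:
        raise ValueError("multiclass report needs at least 2 classes")
    per_class = {c: metric_set(confusion(yt, yp, c)) for c in classes}
    acc = float(np.mean(yt == yp))
    if mcc_mode == "multiclass":
        mcc = float(matthews_corrcoef(yt, yp))
    elif mcc_mode == "macro":
        mcc = float(np.mean([m.mcc for m in per_class.values()]))
    else:
        raise ValueError(f"unknown mcc_mode {mcc_mode!r}")
    return MulticlassReport(per_class=per_class, acc=acc, mcc=mcc)


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the three demonstration classifiers with its hyperparameters."""

    kind: str
    hyperparameters: tuple[tuple[str, Any], ...] = ()
    seed: int = 0

    def build(self) -> Pipeline:
        params = dict(self.hyperparameters)
        if self.kind == "svm":
            clf = SVC(kernel="rbf", gamma="scale", random_state=self.seed, **params)
        elif self.kind == "dt":
            clf = DecisionTreeClassifier(
                criterion="gini", random_state=self.seed, **params
            )
        elif self.kind == "sgd":
            clf = SGDClassifier(
                loss="hinge", max_iter=1000, tol=1e-3, random_state=self.seed, **params
            )
        else:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class CVReport:
    per_fold: list[MetricSet]
    mean: MetricSet
    fold_assignment: np.ndarray
    seed: int
    per_class: dict[Any, MetricSet] | None = None
    selector_info: list[dict[str, Any]] = field(default_factory=list)


def _mean_metrics(sets: Iterable[MetricSet]) -> MetricSet:
    sets = list(sets)
    return MetricSet(
        acc=float(np.mean([m.acc for m in sets])),
        recall=float(np.mean([m.recall for m in sets])),
        precision=float(np.mean([m.precision for m in sets])),
        f_measure=float(np.mean([m.f_measure for m in sets])),
        mcc=float(np.mean([m.mcc for m in sets])),
    )


def cross_validate(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    selector=None,
    folds: int = 5,
    seed: int = 0,
    paper_mode: bool = False,
    positive_code: int | None = None,
) -> CVReport:
    """Stratified k-fold evaluation of one classifier on a FeatureMatrix.

    ``selector`` is an unfitted selector estimator (cloned and refitted on
    each training split unless ``paper_mode``). Binary data reports
    positive-class metrics (default positive = class code 1); multiclass
    data reports pooled accuracy, macro recall/precision/F and the
    generalized multiclass MCC per fold, plus mean per-class metrics.
    """
    X, y = matrix.X, matrix.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {matrix.classes[small]!r} has {counts.min()} samples; "
            f"need at least {folds} for {folds}-fold stratified CV"
        )
    binary = classes.size == 2
    if positive_code is None:
        positive_code = 1
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignment = np.empty(len(y), dtype=int)
    fixed_indices: list[int] | None = None
    selector_info: list[dict[str, Any]] = []
    if selector is not None and paper_mode:
        fitted = clone(selector).fit(X, y)
        fixed_indices = list(fitted.selected_)
        selector_info.append({"fold": "all", "n_selected": len(fixed_indices)})
    per_fold: list[MetricSet] = []
    fold_class_reports: list[dict[Any, MetricSet]] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_assignment[te] = fold
        if selector is None:
            Xtr, Xte = X[tr], X[te]
        elif fixed_indices is not None:
            Xtr, Xte = X[tr][:, fixed_indices], X[te][:, fixed_indices]
        else:
            sel = clone(selector).fit(X[tr], y[tr])
            idx = list(sel.selected_)
            selector_info.append({"fold": fold, "n_selected": len(idx)})
            Xtr, Xte = X[tr][:, idx], X[te][:, idx]
        model = spec.build()
        model.fit(Xtr, y[tr])
        pred = model.predict(Xte)
        if binary:
            per_fold.append(metric_set(confusion(y[te], pred, positive_code)))
        else:
            rep = multiclass_report(y[te], pred)
            macro = _mean_metrics(rep.per_class.values())
            per_fold.append(
                MetricSet(acc=rep.acc, recall=macro.recall,
                          precision=macro.precision, f_measure=macro.f_measure,
                          mcc=rep.mcc)
            )
            fold_class_reports.append(rep.per_class)
    per_class = None
    if fold_class_reports:
        per_class = {}
        for c in classes:
            per_class[int(c)] = _mean_metrics(
                rep[c] for rep in fold_class_reports if c in rep
            )
    return CVReport(
        per_fold=per_fold,
        mean=_mean_metrics(per_fold),
        fold_assignment=fold_assignment,
        seed=seed,
        per_class=per_class,
        selector_info=selector_info,
    )


def alpha_sweep(
    records: Sequence[ProteinRecord],
    labels,
    alphas: Sequence[float] | None = None,
    specs: Sequence[ClassifierSpec] | None = None,
    selector=None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV accuracy over a grid of fusion coefficients and classifiers.

    Default grid is alpha = 0.0, 0.1, ..., 1.0 with the three demonstration
    classifiers; returns a tidy table (alpha, classifier, mean_acc, mean_mcc)
    with ascending alpha within each classifier block.
    """
    if alphas is None:
        alphas = np.round(np.arange(0.0, 1.01, 0.1), 10)
    if specs is None:
        specs = [ClassifierSpec("svm", seed=seed), ClassifierSpec("dt", seed=seed),
                 ClassifierSpec("sgd", seed=seed)]
    rows = []
    for spec in specs:
        for alpha in alphas:
            matrix = encode_dataset(records, labels, alpha=float(alpha))
            report = cross_validate(
                matrix, spec, selector=selector, folds=folds, seed=seed
            )
            rows.append(
                {"classifier": spec.kind, "alpha": float(alpha),
                 "mean_acc": report.mean.acc, "mean_mcc": report.mean.mcc}
            )
    return pd.DataFrame(rows)


DEFAULT_SWEEP_ALPHA = DEFAULT_ALPHA  # re-export for CLI convenience
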