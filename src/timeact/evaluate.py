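"""Confusion matrices, per-class metrics, cross-validation, transfer.

Conventions: rows are the manually-coded (truth) labels, columns the
modeled (predicted) labels, in the fixed class order indoor / outdoor
static / outdoor walking / in-vehicle travel.  Published contingency tables
sometimes print the transposed layout; :meth:`ConfusionMatrix.oriented`
normalizes either convention before metrics are computed.  Transposing a
matrix swaps sensitivity and precision, which is exactly how the two
printed conventions can be told apart arithmetically.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .rulebased import CLASS_ORDER

__all__ = ["ConfusionMatrix", "MetricReport", "confusion_matrix", "metrics",
           "repeated_kfold", "cross_dataset_eval"]


@dataclass
class ConfusionMatrix:
    """4x4 counts; ``counts[i, j]`` = points coded as class i, modeled as j."""

    counts: np.ndarray
    classes: tuple = CLASS_ORDER
    transposed_source: bool = False   # printed table had modeled rows

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}x{k} counts, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def oriented(self) -> "ConfusionMatrix":
        """Counts in the canonical rows=coded orientation."""
        if self.transposed_source:
            return ConfusionMatrix(self.counts.T, self.classes, False)
        return self

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        a, b = self.oriented(), other.oriented()
        if a.classes != b.classes:
            raise ValueError("class order mismatch")
        return ConfusionMatrix(a.counts + b.counts, a.classes)

    def to_frame(self) -> pd.DataFrame:
        cm = self.oriented()
        return pd.DataFrame(cm.counts,
                            index=[f"{c} (coded)" for c in cm.classes],
                            columns=[f"{c} (modeled)" for c in cm.classes])


@dataclass
class MetricReport:
    """Per-class sensitivity / specificity / precision in percent."""

    sensitivity_pct: dict[str, float]
    specificity_pct: dict[str, float]
    precision_pct: dict[str, float]
    share_pct: dict[str, float]
    total: int
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "precision_pct": self.precision_pct,
            "share_pct": self.share_pct,
            "undefined": self.undefined,
        }


def confusion_matrix(truth, predicted, classes=CLASS_ORDER) -> ConfusionMatrix:
    """Tally coded-versus-modeled label pairs."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label outside the class set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity, specificity and precision per class, in percent.

    sensitivity = diag / row sum (recall); precision = diag / column sum;
    specificity = TN / (TN + FP) where FP is the off-diagonal column mass.
    Zero denominators yield NaN and are listed in ``undefined``.
    """
    cm = cm.oriented()
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    diag = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    tn = total - row - col + diag
    fp = col - diag

    undefined = []

    def pct(num, den, cls, name):
        if den == 0:
            undefined.append(f"{name}:{cls}")
            return float("nan")
        return float(num / den * 100.0)

    sens, spec, prec, share = {}, {}, {}, {}
    for i, cls in enumerate(cm.classes):
        sens[cls] = pct(diag[i], row[i], cls, "sensitivity")
        prec[cls] = pct(diag[i], col[i], cls, "precision")
        spec[cls] = pct(tn[i], tn[i] + fp[i], cls, "specificity")
        share[cls] = float(row[i] / total * 100.0)
    return MetricReport(sens, spec, prec, share, int(total), undefined)


def repeated_kfold(features: pd.DataFrame, labels, train_fn, predict_fn,
                   k: int = 10, repeats: int = 1, seed: int = 0,
                   stratified: bool = True,
                   ) -> tuple[ConfusionMatrix, MetricReport]:
    """k-fold cross-validation with pooled (micro-averaged) counts.

    ``train_fn(X, y) -> model`` and ``predict_fn(model, X) -> labels`` keep
    the harness model-agnostic.  Counts are pooled over all folds and
    repeats, then metrics are computed once on the pooled matrix.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels, dtype=object)
    for cls in set(labels):
        if (labels == cls).sum() < k:
            import logging
            logging.getLogger(__name__).warning(
                "class %r has fewer than k=%d points", cls, k)
    pooled = ConfusionMatrix(np.zeros((len(CLASS_ORDER),) * 2, dtype=np.int64))
    for r in range(repeats):
        splitter_seed = seed + r
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=splitter_seed)
            split = splitter.split(features, labels)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=splitter_seed)
            split = splitter.split(features)
        for train_idx, test_idx in split:
            model = train_fn(features.iloc[train_idx], labels[train_idx])
            pred = predict_fn(model, features.iloc[test_idx])
            pooled = pooled + confusion_matrix(labels[test_idx], pred)
    return pooled, metrics(pooled)


def cross_dataset_eval(model, features_b: pd.DataFrame, labels_b,
                       predict_fn) -> tuple[ConfusionMatrix, MetricReport]:
    """Apply a model trained on dataset A to labeled dataset B, no refit."""
    pred = predict_fn(model, features_b)
    cm = confusion_matrix(np.asarray(labels_b, dtype=object), pred)
    return cm, metrics(cm)
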