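"""Leave-one-out SVM discrimination of MCI converters from nonconverters.

Features are the values of voxels showing a significant group difference
(FCS and/or seed-connectivity maps); each leave-one-out fold standardizes
features on the training subjects only, trains a linear support vector
machine (C = 1 by default), and predicts the held-out subject.  Accuracy,
sensitivity and specificity are computed from the pooled confusion counts
in exact rational arithmetic:

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

with TP/FN counting converter-labeled subjects and TN/FP counting
nonconverter-labeled subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "ClassificationResult",
    "extract_features",
    "loocv_svm",
    "confusion_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ClassificationResult:
    predictions: np.ndarray
    confusion: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float


def extract_features(
    maps: Sequence[np.ndarray], significant_voxel_mask: np.ndarray
) -> np.ndarray:
    """Subjects x features matrix gathered over the significant voxels.

    Feature order is the C order of the mask's True voxels; subject order
    follows ``maps``.
    """
    mask = np.asarray(significant_voxel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty significance mask")
    rows = []
    for m in maps:
        arr = getattr(m, "values", m)
        rows.append(np.asarray(arr)[mask])
    return np.asarray(rows, dtype=float)


def confusion_metrics(c: ConfusionCounts) -> tuple[Fraction, Fraction, Fraction]:
    """Exact (accuracy, sensitivity, specificity) as rational numbers."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    if c.tp + c.fn == 0:
        raise ValueError("no positive-labeled subjects: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no negative-labeled subjects: specificity undefined")
    accuracy = Fraction(c.tp + c.tn, c.total)
    sensitivity = Fraction(c.tp, c.tp + c.fn)
    specificity = Fraction(c.tn, c.tn + c.fp)
    return accuracy, sensitivity, specificity


def loocv_svm(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    balanced: bool = False,
) -> ClassificationResult:
    """Leave-one-out cross-validated SVM; label 1 = converter (positive).

    Standardization statistics are fit on each training fold only, so the
    held-out subject never leaks into its own fold's scaling or model.
    Deterministic given features, labels and configuration.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = features.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must align with feature rows")
    classes = np.unique(labels)
    if set(classes.tolist()) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    if min(np.bincount(labels)) < 2:
        raise ValueError("need at least 2 subjects per class")

    predictions = np.empty(n, dtype=int)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        scaler = StandardScaler().fit(features[train])
        clf = SVC(
            kernel=kernel,
            C=C,
            class_weight="balanced" if balanced else None,
        )
        clf.fit(scaler.transform(features[train]), labels[train])
        predictions[i] = clf.predict(scaler.transform(features[i : i + 1]))[0]

    tp = int(((labels == 1) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions != 1)).sum())
    tn = int(((labels != 1) & (predictions != 1)).sum())
    fp = int(((labels != 1) & (predictions == 1)).sum())
    confusion = ConfusionCounts(tp, fn, tn, fp)
    acc, sens, spec = confusion_metrics(confusion)
    return ClassificationResult(
        predictions=predictions,
        confusion=confusion,
        accuracy=float(acc),
        sensitivity=float(sens),
        specificity=float(spec),
    )
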