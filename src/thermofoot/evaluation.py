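"""Stratified k-fold splitting, confusion matrices and class-wise metrics.

Per-class metrics are one-vs-rest: for class c, TP is the diagonal entry,
FN the rest of row c, FP the rest of column c, TN everything else.  The
per-class accuracy is (TP+TN)/N under that one-vs-rest reading.  The macro
row is the arithmetic mean over defined classes.  Reports print at four
decimals (half away from zero); machine-readable output keeps full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "FoldSplit",
    "ClassMetrics",
    "EvalReport",
    "stratified_folds",
    "confusion",
    "classwise_metrics",
    "macro_average",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "specificity", "sensitivity", "precision", "f_measure")


@dataclass
class FoldSplit:
    assignments: np.ndarray  # fold id per sample
    k: int
    seed: int

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def val_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def __iter__(self):
        for fold in range(self.k):
            yield fold, self.train_indices(fold), self.val_indices(fold)


def stratified_folds(labels, k: int, seed: int = 0) -> FoldSplit:
    """Seeded shuffle within each class, then round-robin over the k folds.

    Guarantees per-fold class counts within one sample of each other.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    short = classes[counts < k]
    if len(short):
        raise ValueError(
            f"class {short[0]} has only {counts[classes == short[0]][0]} samples, "
            f"fewer than k={k}"
        )
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(labels), dtype=int)
    offset = 0
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignments[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # stagger classes so small-class leftovers spread out
    return FoldSplit(assignments=assignments, k=k, seed=seed)


def confusion(y_true, y_pred, num_classes: int) -> np.ndarray:
    """KxK count matrix; rows are true classes, columns predicted classes."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if len(y) and (y.min() < 0 or y.max() >= num_classes):
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class ClassMetrics:
    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    f_measure: float
    support: int
    defined: bool = True

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class EvalReport:
    per_class: dict[int, ClassMetrics]
    confusion_matrix: np.ndarray
    fold: int | None = None
    meta: dict = field(default_factory=dict)

    def macro(self) -> dict[str, float]:
        return macro_average(self)

    def to_frame(self, decimals: int | None = 4) -> pd.DataFrame:
        rows = []
        for cls, m in sorted(self.per_class.items()):
            rows.append({"class": f"Class {cls}", **m.as_dict()})
        rows.append({"class": "Average", **self.macro()})
        df = pd.DataFrame(rows).set_index("class")
        if decimals is not None:
            df = df.map(lambda v: _round_half_up(v, decimals))
        return df

    def to_json_dict(self) -> dict:
        return {
            "fold": self.fold,
            "per_class": {
                str(c): {**m.as_dict(), "support": m.support, "defined": m.defined}
                for c, m in sorted(self.per_class.items())
            },
            "macro": self.macro(),
            "confusion_matrix": self.confusion_matrix.tolist(),
        }


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def classwise_metrics(cm: np.ndarray, fold: int | None = None) -> EvalReport:
    """One-vs-rest accuracy/specificity/sensitivity/precision/F per class.

    A class with zero true and zero predicted samples gets undefined metrics;
    it is excluded from the macro average with a warning.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = int(cm.sum())
    if n == 0:
        raise ValueError("confusion matrix is empty")
    per_class: dict[int, ClassMetrics] = {}
    for c in range(cm.shape[0]):
        tp = int(cm[c, c])
        fn = int(cm[c].sum()) - tp
        fp = int(cm[:, c].sum()) - tp
        tn = n - tp - fn - fp
        if tp + fn + fp == 0:
            warnings.warn(
                f"class {c} has no true or predicted samples; metrics undefined",
                stacklevel=2,
            )
            per_class[c] = ClassMetrics(
                accuracy=float("nan"), specificity=float("nan"),
                sensitivity=float("nan"), precision=float("nan"),
                f_measure=float("nan"), support=0, defined=False,
            )
            continue
        sens = _safe_div(tp, tp + fn)
        prec = _safe_div(tp, tp + fp)
        per_class[c] = ClassMetrics(
            accuracy=(tp + tn) / n,
            specificity=_safe_div(tn, tn + fp),
            sensitivity=sens,
            precision=prec,
            f_measure=_safe_div(2 * prec * sens, prec + sens),
            support=tp + fn,
        )
    return EvalReport(per_class=per_class, confusion_matrix=cm.astype(int), fold=fold)


def macro_average(report: EvalReport) -> dict[str, float]:
    """Arithmetic mean of each metric over the defined classes."""
    defined = [m for m in report.per_class.values() if m.defined]
    if not defined:
        raise ValueError("no defined classes to average")
    return {
        name: float(np.mean([getattr(m, name) for m in defined]))
        for name in METRIC_NAMES
    }
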