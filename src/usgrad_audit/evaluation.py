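"""Classification metrics: confusion matrix, per-class and averaged scores,
and the same metrics stratified by consensus attention category.

Per-class precision (positive predictive value), sensitivity (recall) and
F1 are expressed as percentages; macro averages weight every station
equally while weighted averages use each station's support, so for
single-label multiclass prediction the weighted sensitivity equals the
overall accuracy exactly (the micro identity). Metrics are kept at full
precision internally and rounded half-away-from-zero to one decimal only at
report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from usgrad_audit.annotation import AnnotationLabel
from usgrad_audit.phantom import STATIONS


def round1(x: float) -> float:
    """Round half away from zero to one decimal (table convention)."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclass
class ClassMetrics:
    station: str
    precision: float     # percent
    sensitivity: float   # percent
    f1: float            # percent
    support: int
    flags: tuple[str, ...] = ()


@dataclass
class AggregateMetrics:
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    n_images: int

    def to_dict(self) -> dict:
        return {
            "accuracy": round1(self.accuracy),
            "macro": {k: round1(v) for k, v in self.macro.items()},
            "weighted": {k: round1(v) for k, v in self.weighted.items()},
            "n_images": self.n_images,
        }


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              class_order: Sequence[str] = STATIONS) -> np.ndarray:
    """Confusion matrix with rows = true station, columns = predicted."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    known = set(class_order)
    unknown = (set(true_labels) | set(predicted_labels)) - known
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(unknown)}")
    return _sk_confusion(true_labels, predicted_labels, labels=list(class_order))


def per_class(cm: np.ndarray, class_order: Sequence[str] = STATIONS) -> list[ClassMetrics]:
    """Precision/sensitivity/F1 (percent) and support for each class.

    Zero-denominator cases return 0 and are flagged rather than NaN-ing
    the table.
    """
    cm = np.asarray(cm)
    out = []
    for i, cls in enumerate(class_order):
        tp = float(cm[i, i])
        fp = float(cm[:, i].sum() - tp)
        fn = float(cm[i, :].sum() - tp)
        flags = []
        if tp + fp > 0:
            prec = 100.0 * tp / (tp + fp)
        else:
            prec = 0.0
            flags.append("no_predicted_positives")
        if tp + fn > 0:
            sens = 100.0 * tp / (tp + fn)
        else:
            sens = 0.0
            flags.append("no_true_positives")
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        out.append(ClassMetrics(station=str(cls), precision=prec, sensitivity=sens,
                                f1=f1, support=int(cm[i, :].sum()), flags=tuple(flags)))
    return out


def macro_average(metrics: Sequence[ClassMetrics]) -> dict[str, float]:
    """Unweighted mean of each metric over classes (equal station weight)."""
    n = len(metrics)
    return {
        "precision": sum(m.precision for m in metrics) / n,
        "sensitivity": sum(m.sensitivity for m in metrics) / n,
        "f1": sum(m.f1 for m in metrics) / n,
    }


def weighted_average(metrics: Sequence[ClassMetrics]) -> dict[str, float]:
    """Support-weighted mean of each metric over classes."""
    total = sum(m.support for m in metrics)
    if total <= 0:
        raise ValueError("total support must be positive")
    return {
        "precision": sum(m.precision * m.support for m in metrics) / total,
        "sensitivity": sum(m.sensitivity * m.support for m in metrics) / total,
        "f1": sum(m.f1 * m.support for m in metrics) / total,
    }


def aggregate(cm: np.ndarray, class_order: Sequence[str] = STATIONS,
              restrict_to_present: bool = False) -> AggregateMetrics:
    """Accuracy plus macro and weighted averages from a confusion matrix.

    With `restrict_to_present`, macro averaging runs over classes with
    non-zero support only (used within attention-category strata, where
    not every station need appear).
    """
    cm = np.asarray(cm)
    n = int(cm.sum())
    if n == 0:
        raise ValueError("empty confusion matrix")
    metrics = per_class(cm, class_order)
    macro_pool = [m for m in metrics if m.support > 0] if restrict_to_present else metrics
    return AggregateMetrics(
        accuracy=100.0 * float(np.trace(cm)) / n,
        macro=macro_average(macro_pool),
        weighted=weighted_average([m for m in metrics if m.support > 0]),
        n_images=n,
    )


def stratify(true_labels: Sequence[str], predicted_labels: Sequence[str],
             consensus_labels: Sequence, class_order: Sequence[str] = STATIONS,
             averaging: str = "macro") -> dict[str, AggregateMetrics]:
    """Classification metrics within each consensus attention category.

    `consensus_labels` aligns with the label sequences and must be fully
    adjudicated; pending items are an error listing the offending indices.
    Within each stratum, precision/sensitivity/F1 use macro averaging over
    the stations present (``averaging='weighted'`` switches to
    support-weighted averaging).
    """
    if not len(true_labels) == len(predicted_labels) == len(consensus_labels):
        raise ValueError("inputs differ in length")
    if averaging not in ("macro", "weighted"):
        raise ValueError("averaging must be 'macro' or 'weighted'")
    pending = [i for i, c in enumerate(consensus_labels)
               if c is None or getattr(c, "final_label", c) is None]
    if pending:
        raise ValueError(f"pending consensus items at indices {pending[:10]}")

    finals = []
    for c in consensus_labels:
        lab = getattr(c, "final_label", c)
        finals.append(AnnotationLabel(lab).value)

    out: dict[str, AggregateMetrics] = {}
    for cat in sorted(set(finals)):
        sel = [i for i, f in enumerate(finals) if f == cat]
        cm = confusion([true_labels[i] for i in sel],
                       [predicted_labels[i] for i in sel], class_order)
        agg = aggregate(cm, class_order, restrict_to_present=True)
        if averaging == "weighted":
            agg = AggregateMetrics(accuracy=agg.accuracy, macro=agg.weighted,
                                   weighted=agg.weighted, n_images=agg.n_images)
        out[cat] = agg
    return out
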