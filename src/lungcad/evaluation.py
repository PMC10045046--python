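"""Confusion-matrix metrics and learning-curve reports.

Metrics follow the standard clinical definitions on (TP, TN, FP, FN) counts
with malignant as the positive class: accuracy, sensitivity (recall of the
diseased), specificity (recall of the healthy), precision, and the F-score
as the harmonic mean of precision and sensitivity.  All are reported as
percentages.  A metric whose denominator is zero is reported as an explicit
``None`` marker — never silently as zero — and serialized as the string
"undefined".
"""

from __future__ import annotations

import dataclasses
import json
from typing import Dict, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "classification_metrics",
    "evaluate_predictions",
    "learning_curve",
    "UNDEFINED",
]

UNDEFINED = "undefined"
DEFAULT_LABELS = ("benign", "malignant")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass(frozen=True)
class MetricReport:
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f_score: Optional[float]
    n: int

    def to_dict(self) -> Dict[str, object]:
        def enc(v):
            return UNDEFINED if v is None else v
        return {"accuracy": enc(self.accuracy),
                "sensitivity": enc(self.sensitivity),
                "specificity": enc(self.specificity),
                "precision": enc(self.precision),
                "f_score": enc(self.f_score), "n": self.n}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def confusion_counts(predicted: Sequence, truth: Sequence,
                     positive_class="malignant",
                     allowed_labels: Sequence = DEFAULT_LABELS) -> ConfusionCounts:
    """Standard TP/TN/FP/FN counting with the stated positive class."""
    predicted, truth = list(predicted), list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    if not predicted:
        raise ValueError("empty label lists")
    allowed = set(allowed_labels)
    for l in list(predicted) + list(truth):
        if l not in allowed:
            raise ValueError(f"label {l!r} outside {sorted(allowed)}")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Percent metrics from a confusion table; zero denominators -> None."""
    if c.n == 0:
        raise ValueError("all-zero confusion counts")
    accuracy = _ratio(c.tp + c.tn, c.n)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    precision = _ratio(c.tp, c.tp + c.fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f_score: Optional[float] = None
    else:
        f_score = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricReport(accuracy=accuracy, sensitivity=sensitivity,
                        specificity=specificity, precision=precision,
                        f_score=f_score, n=c.n)


def evaluate_predictions(predicted: Sequence, truth: Sequence,
                         positive_class="malignant",
                         allowed_labels: Sequence = DEFAULT_LABELS) -> MetricReport:
    return classification_metrics(
        confusion_counts(predicted, truth, positive_class, allowed_labels))


def learning_curve(samples, train_sizes: Sequence[int], train_eval_fn,
                   seed: int = 0):
    """Metric-vs-training-size table (one row per requested size).

    The independent axis is the *training-set* size: for each requested size
    a stratified split reserves 20% of the full set for testing, the
    training subset is truncated to the size, and ``train_eval_fn(train,
    test, seed)`` must return a :class:`MetricReport`.  Returns a DataFrame
    mirroring the usual metric-vs-instances report axes.
    """
    import pandas as pd

    from .mlcnn import split_dataset

    labels = [s.label for s in samples]
    split = split_dataset(labels, fraction=0.8, seed=seed)
    rows = []
    for size in train_sizes:
        train_idx = split.train_indices[:size]
        train = [samples[i] for i in train_idx]
        test = [samples[i] for i in split.test_indices]
        report = train_eval_fn(train, test, seed)
        row = {"n_instances": len(train)}
        row.update(report.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
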