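"""Confusion-matrix metrics and tabular report assembly.

accuracy = (TP + TN) / (TP + TN + FP + FN)
sensitivity = TP / (TP + FN),  specificity = TN / (TN + FP)
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Accuracy, sensitivity and specificity are reported as percentages; MCC is
a correlation in [-1, 1].  When any factor of the MCC denominator is
zero, MCC is defined as 0 (no information) and a warning is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


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


def confusion(truth, pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN (positive class = 1 = PD)."""
    truth = np.asarray(truth).astype(int)
    pred = np.asarray(pred).astype(int)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred lengths differ")
    if not (np.isin(truth, (0, 1)).all() and np.isin(pred, (0, 1)).all()):
        raise ValueError("labels must be binary")
    return ConfusionCounts(
        tp=int(((truth == 1) & (pred == 1)).sum()),
        tn=int(((truth == 0) & (pred == 0)).sum()),
        fp=int(((truth == 0) & (pred == 1)).sum()),
        fn=int(((truth == 1) & (pred == 0)).sum()),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Full-precision metrics; percentages on the 0-100 scale."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float

    def round_trip(self) -> dict:
        """Report-precision view: percentages to 2 decimals, MCC to 4."""
        return {
            "accuracy": round(self.accuracy, 2),
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "mcc": round(self.mcc, 4),
        }


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy / sensitivity / specificity / MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("no predictions to score")
    acc = 100.0 * (c.tp + c.tn) / c.total
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        log.warning("MCC denominator has a zero factor; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(c, acc, sens, spec, mcc)


def metrics_frame(rows: dict[str, MetricsReport]) -> pd.DataFrame:
    """One row per configuration: scheme/classifier label, metrics columns."""
    recs = []
    for label, m in rows.items():
        recs.append(
            {
                "configuration": label,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "mcc": m.mcc,
                "tp": m.counts.tp,
                "tn": m.counts.tn,
                "fp": m.counts.fp,
                "fn": m.counts.fn,
            }
        )
    return pd.DataFrame(recs)


def per_test_accuracy_table(accuracies: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a (test_id x classifier) accuracy table.

    Adds ``mean`` (1 decimal) and ``sd`` (sample, n-1) columns across the
    classifier columns.  With a single classifier column the SD is
    undefined and reported as 0 with a warning.  Raw accuracies are
    returned untouched alongside the aggregates.
    """
    if accuracies.shape[1] < 1:
        raise ValueError("need at least one classifier column")
    out = accuracies.copy()
    if accuracies.shape[1] == 1:
        log.warning("single classifier column: per-test SD undefined, reported as 0")
        sd = pd.Series(0.0, index=accuracies.index)
    else:
        sd = accuracies.std(axis=1, ddof=1)
    out["mean"] = accuracies.mean(axis=1).round(1)
    out["sd"] = sd
    return out
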