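"""Confusion-matrix indices, empirical ROC/Az and paired model comparison.

The positive class is *tear* throughout.  Five indices are reported —
accuracy, sensitivity, specificity, PPV and NPV — plus the empirical area
under the ROC curve (Az).  For display the indices are truncated (floored)
to integer percent; raw proportions are always kept alongside.

Az is computed from the empirical ROC (threshold sweep over the observed
scores, trapezoidal area), which is identical to the tie-corrected
all-pairs probability that a random tear scores above a random
tendinopathy.  No binormal-MLE curve fitting is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import roc_curve

from .classifier import NEGATIVE_LABEL, POSITIVE_LABEL


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    """The five indices as raw proportions (nan where the denominator is 0)."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    az: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "az": self.az,
        }


def truncate_percent(proportion: float) -> int:
    """Display convention: proportions are floored to integer percent
    (175/191 = 91.62% prints as 91%)."""
    if math.isnan(proportion):
        raise ValueError("cannot display an undefined proportion")
    return int(math.floor(100.0 * proportion))


def _labels01(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "UOS":
        known = {POSITIVE_LABEL, NEGATIVE_LABEL}
        if not set(arr.tolist()) <= known:
            raise ValueError(f"labels must be within {known}")
        return (arr == POSITIVE_LABEL).astype(int)
    return arr.astype(int)


def confusion(predicted, truth) -> ConfusionCounts:
    """Tally a confusion matrix (positive class = tear)."""
    pred = _labels01(predicted)
    true = _labels01(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth lengths differ")
    return ConfusionCounts(
        tp=int(((pred == 1) & (true == 1)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def performance(c: ConfusionCounts, az: float = math.nan) -> PerformanceReport:
    """The five indices of a confusion matrix; empty denominators give nan."""
    return PerformanceReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        az=az,
    )


def roc_and_az(scores, truth) -> tuple[np.ndarray, float]:
    """Empirical ROC points and trapezoidal area under the curve.

    Returns ``(points, az)`` where `points` is an array of (FPR, TPR)
    pairs from (0, 0) to (1, 1).  Ties in the scores contribute half
    credit, so `az` equals the all-pairs Mann-Whitney probability.
    """
    y = _labels01(truth)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    az = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), az


def compare_paired(predicted_a, predicted_b, truth) -> float:
    """Exact McNemar p-value for two models' paired correctness.

    Only discordant cases (one model right, the other wrong) inform the
    test: under the null their split is Binomial(n_discordant, 1/2).
    """
    pa = _labels01(predicted_a)
    pb = _labels01(predicted_b)
    t = _labels01(truth)
    if not (pa.shape == pb.shape == t.shape):
        raise ValueError("prediction and truth lengths differ")
    correct_a = pa == t
    correct_b = pb == t
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    if b + c == 0:
        return 1.0
    return float(binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue)


def format_report(reports: dict[str, PerformanceReport],
                  counts: dict[str, ConfusionCounts]) -> str:
    """Plain-text table of the five indices and Az, one column per model."""
    names = list(reports)
    lines = ["\t" + "\t".join(names)]
    rows = [
        ("Accuracy", lambda c: (c.tp + c.tn, c.total)),
        ("Sensitivity", lambda c: (c.tp, c.tp + c.fn)),
        ("Specificity", lambda c: (c.tn, c.tn + c.fp)),
        ("PPV", lambda c: (c.tp, c.tp + c.fp)),
        ("NPV", lambda c: (c.tn, c.tn + c.fn)),
    ]
    for label, num_den in rows:
        cells = []
        for name in names:
            num, den = num_den(counts[name])
            cells.append(
                f"{truncate_percent(_ratio(num, den))}% ({num}/{den})"
                if den > 0
                else "n/a"
            )
        lines.append(label + "\t" + "\t".join(cells))
    lines.append(
        "Az\t" + "\t".join(
            f"{reports[name].az:.4f}" if not math.isnan(reports[name].az) else "n/a"
            for name in names
        )
    )
    return "\n".join(lines)
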