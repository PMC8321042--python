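"""Slide-level binary classification metrics.

Single-class (HER2-positive) accuracy, precision, recall and F1 from the
confusion matrix, with undefined ratios (zero denominator) reported as
absent — never silently zero. Also provides the inverse problem: recovering
the unique integer confusion matrix consistent with rounded precision/recall
on a known class split, which makes printed metric tables checkable for
internal consistency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Confusion matrix and derived metrics; None marks an undefined ratio."""

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def to_dict(self) -> Dict[str, object]:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }

    def summary(self) -> str:
        def fmt(x: Optional[float]) -> str:
            return "undefined" if x is None else f"{x:.3f}"

        return (
            f"n={self.n}  TP={self.TP} FP={self.FP} TN={self.TN} FN={self.FN}\n"
            f"accuracy={fmt(self.accuracy)}  precision={fmt(self.precision)}  "
            f"recall={fmt(self.recall)}  f1={fmt(self.f1)}"
        )


def f1_from_pr(precision: float, recall: float) -> Optional[float]:
    """Harmonic mean 2PR/(P+R); None (with a warning) when both are zero."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        warnings.warn("F1 undefined: precision and recall are both zero")
        return None
    return 2.0 * precision * recall / (precision + recall)


def report_from_confusion(TP: int, FP: int, TN: int, FN: int) -> EvaluationReport:
    n = TP + FP + TN + FN
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (TP + TN) / n
    precision = TP / (TP + FP) if TP + FP > 0 else None
    recall = TP / (TP + FN) if TP + FN > 0 else None
    if precision is None or recall is None:
        f1 = None
        warnings.warn("precision or recall undefined (zero denominator)")
    elif precision + recall == 0:
        f1 = None
    else:
        f1 = f1_from_pr(precision, recall)
    return EvaluationReport(TP, FP, TN, FN, accuracy, precision, recall, f1)


def evaluate(predictions: Dict[str, int], truth: Dict[str, int]) -> EvaluationReport:
    """Compare per-slide binary calls against ground truth.

    The two maps must cover exactly the same slides; mismatched key sets are
    rejected listing the differences.
    """
    only_pred = sorted(set(predictions) - set(truth))
    only_truth = sorted(set(truth) - set(predictions))
    if only_pred or only_truth:
        raise ValueError(
            f"slide sets differ: only in predictions {only_pred}; "
            f"only in truth {only_truth}"
        )
    TP = FP = TN = FN = 0
    for sid, yhat in predictions.items():
        y = truth[sid]
        if y == 1 and yhat == 1:
            TP += 1
        elif y == 0 and yhat == 1:
            FP += 1
        elif y == 0 and yhat == 0:
            TN += 1
        else:
            FN += 1
    return report_from_confusion(TP, FP, TN, FN)


def consistent_confusion_matrix(
    precision: float,
    recall: float,
    n_positive: int,
    n_negative: int,
    decimals: int = 3,
) -> Tuple[int, int, int, int]:
    """The integer confusion matrix reproducing rounded precision and recall.

    Enumerates all (TP, FP) on a fixed class split and returns the unique
    matrix whose metrics round to the given values at ``decimals`` places.
    Raises if no matrix or more than one matrix matches.
    """
    matches: List[Tuple[int, int, int, int]] = []
    for TP in range(n_positive + 1):
        FN = n_positive - TP
        for FP in range(n_negative + 1):
            TN = n_negative - FP
            if TP + FP == 0:
                continue
            p = TP / (TP + FP)
            r = TP / n_positive
            if round(p, decimals) == round(precision, decimals) and round(
                r, decimals
            ) == round(recall, decimals):
                matches.append((TP, FP, TN, FN))
    if not matches:
        raise ValueError(
            f"no confusion matrix on {n_positive}+/{n_negative}- reproduces "
            f"precision={precision}, recall={recall}"
        )
    if len(matches) > 1:
        raise ValueError(f"ambiguous: {len(matches)} matrices match: {matches}")
    return matches[0]
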