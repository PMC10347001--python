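"""Multiclass evaluation: accuracy, macro metrics, row-normalized confusion.

All quantities derive from the 4x4 count matrix n_ij (true phase i
recognized as phase j).  The confusion matrix reported here is row
normalized, c_ij = n_ij / n_i, so each row with support sums to one.
Precision, recall and F1 are computed one-vs-rest per phase; the macro
aggregate takes unweighted means of per-class precision and recall, and the
macro-F1 is the *harmonic mean of those two macro means* — which is not the
same number as the mean of per-class F1 scores whenever errors are
asymmetric, so the per-class mean is also reported alongside for
comparison.  Zero denominators (a phase never predicted, or absent from the
truth) yield a metric of 0 with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_counts

from .phases import N_PHASES, PHASE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Full evaluation of one prediction track against truth."""

    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    class_accuracy: np.ndarray  # one-vs-rest (TP+TN)/(TP+TN+FP+FN)
    macro_precision: float
    macro_recall: float
    macro_f1: float  # harmonic mean of the two macro means
    macro_f1_classwise: float  # unweighted mean of per-class F1, for comparison
    confusion: np.ndarray  # row-normalized c_ij
    counts: np.ndarray  # raw n_ij
    support: np.ndarray  # n_i
    class_names: tuple[str, ...] = field(default=PHASE_NAMES)

    def to_dict(self) -> dict:
        per_class = {
            name: {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "accuracy": float(self.class_accuracy[i]),
                "support": int(self.support[i]),
            }
            for i, name in enumerate(self.class_names)
        }
        return {
            "accuracy": float(self.accuracy),
            "macro_precision": float(self.macro_precision),
            "macro_recall": float(self.macro_recall),
            "macro_f1": float(self.macro_f1),
            "macro_f1_classwise": float(self.macro_f1_classwise),
            "per_class": per_class,
            "confusion": self.confusion.tolist(),
            "counts": self.counts.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=[f"true {n}" for n in self.class_names],
            columns=[f"pred {n}" for n in self.class_names],
        )


def _validated(true, pred) -> tuple[np.ndarray, np.ndarray]:
    true = np.asarray(true, dtype=int).ravel()
    pred = np.asarray(pred, dtype=int).ravel()
    if true.shape != pred.shape:
        raise ValueError(
            f"true and predicted labels differ in length: {len(true)} vs {len(pred)}"
        )
    if true.size == 0:
        raise ValueError("empty label vectors")
    for name, v in (("true", true), ("pred", pred)):
        if v.min() < 0 or v.max() >= N_PHASES:
            raise ValueError(f"{name} labels outside the phase alphabet 0..3")
    return true, pred


def confusion_matrix(true, pred) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-normalized confusion c_ij = n_ij/n_i plus raw counts and support.

    Rows with zero support stay all-zero and are flagged with a warning.
    """
    true, pred = _validated(true, pred)
    counts = _sk_confusion_counts(true, pred, labels=np.arange(N_PHASES))
    support = counts.sum(axis=1)
    empty = support == 0
    if empty.any():
        logger.warning(
            "phase(s) %s absent from the true labels; confusion rows left zero",
            [PHASE_NAMES[i] for i in np.nonzero(empty)[0]],
        )
    conf = np.zeros_like(counts, dtype=float)
    nz = ~empty
    conf[nz] = counts[nz] / support[nz, None]
    return conf, counts, support


def accuracy(true, pred) -> float:
    """Overall multiclass accuracy: fraction of samples recognized correctly."""
    true, pred = _validated(true, pred)
    return float(np.mean(true == pred))


def _per_class(counts: np.ndarray) -> dict[str, np.ndarray]:
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    total = counts.sum()
    tn = total - tp - fp - fn

    def ratio(num, den, what):
        out = np.zeros_like(num)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if (~ok).any():
            logger.warning(
                "%s undefined for phase(s) %s (zero denominator); reported as 0",
                what,
                [PHASE_NAMES[i] for i in np.nonzero(~ok)[0]],
            )
        return out

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "F1")
    class_acc = (tp + tn) / total
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "class_accuracy": class_acc,
    }


def macro_metrics(true, pred) -> tuple[float, float, float]:
    """(macro-precision, macro-recall, macro-F1).

    Macro-P and macro-R are unweighted means over the one-vs-rest per-class
    values; macro-F1 is 2*P*R/(P+R) of those means.
    """
    _, counts, _ = confusion_matrix(true, pred)
    pc = _per_class(counts)
    p = float(np.mean(pc["precision"]))
    r = float(np.mean(pc["recall"]))
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def evaluate(true, pred) -> MetricsReport:
    """The full report for one prediction track."""
    conf, counts, support = confusion_matrix(true, pred)
    pc = _per_class(counts)
    p = float(np.mean(pc["precision"]))
    r = float(np.mean(pc["recall"]))
    macro_f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return MetricsReport(
        accuracy=float(np.trace(counts) / counts.sum()),
        precision=pc["precision"],
        recall=pc["recall"],
        f1=pc["f1"],
        class_accuracy=pc["class_accuracy"],
        macro_precision=p,
        macro_recall=r,
        macro_f1=macro_f1,
        macro_f1_classwise=float(np.mean(pc["f1"])),
        confusion=conf,
        counts=counts,
        support=support,
    )
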