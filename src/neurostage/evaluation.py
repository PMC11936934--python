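"""Per-class classification metrics with macro and weighted averages.

The report mirrors the standard multiclass layout for the dementia-stage
problem: a k x k confusion matrix (rows = true, columns = predicted),
one-vs-rest precision / recall / F1 and AUC per class, overall accuracy, and
macro (unweighted) plus support-weighted averages.  Metric formulas are
delegated to scikit-learn; aggregation and serialisation live here.

Zero-division policy: a class with no support (or no predicted positives)
reports 0 for the affected rate with a logged warning; AUC is ``None`` when
undefined (single-class slice or missing scores) and serialises as JSON null.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .exceptions import ShapeError

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "evaluate_predictions", "write_report", "read_report"]

_METRIC_KEYS = ("precision", "recall", "f1", "auc")


@dataclass
class EvalReport:
    """Confusion matrix, per-class metric dicts, accuracy and the two
    averaging rows."""

    labels: list
    confusion: np.ndarray
    per_class: dict
    accuracy: float
    macro_avg: dict
    weighted_avg: dict

    def to_dict(self) -> dict:
        return {
            "labels": [str(l) for l in self.labels],
            "confusion": self.confusion.tolist(),
            "per_class": {str(k): dict(v) for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_avg": dict(self.macro_avg),
            "weighted_avg": dict(self.weighted_avg),
        }

    @classmethod
    def from_dict(cls, blob: dict) -> "EvalReport":
        return cls(
            labels=list(blob["labels"]),
            confusion=np.asarray(blob["confusion"], dtype=np.int64),
            per_class=blob["per_class"],
            accuracy=blob["accuracy"],
            macro_avg=blob["macro_avg"],
            weighted_avg=blob["weighted_avg"],
        )

    def render_table(self) -> str:
        """Text table with percentages at two decimals."""

        def pct(v) -> str:
            return "n/a" if v is None else f"{100.0 * v:.2f}"

        rows = [f"{'Class':<18}{'Precision (%)':>15}{'Recall (%)':>13}{'F1-score (%)':>15}{'AUC (%)':>10}"]
        for label in self.labels:
            m = self.per_class[label] if label in self.per_class else self.per_class[str(label)]
            rows.append(
                f"{str(label):<18}{pct(m['precision']):>15}{pct(m['recall']):>13}"
                f"{pct(m['f1']):>15}{pct(m['auc']):>10}"
            )
        rows.append(f"{'Accuracy':<18}{pct(self.accuracy):>15}")
        for name, avg in (("Macro average", self.macro_avg), ("Weighted average", self.weighted_avg)):
            rows.append(
                f"{name:<18}{pct(avg['precision']):>15}{pct(avg['recall']):>13}"
                f"{pct(avg['f1']):>15}{pct(avg['auc']):>10}"
            )
        return "\n".join(rows)


def _average(values, weights=None):
    """Mean skipping ``None`` entries; returns ``None`` if nothing remains."""
    pairs = [
        (v, 1.0 if weights is None else weights[i])
        for i, v in enumerate(values)
        if v is not None
    ]
    if not pairs:
        return None
    total = sum(w for _, w in pairs)
    if total == 0:
        return None
    return sum(v * w for v, w in pairs) / total


def evaluate_predictions(y_true, y_pred, scores=None, labels=None) -> EvalReport:
    """Full multiclass report from labels and (optionally) per-class scores.

    ``scores`` is an ``n x k`` matrix aligned with ``labels`` (sorted unique
    labels when not given); AUC is the one-vs-rest ROC area per class and is
    reported as ``None`` when scores are absent or a class has no support.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"y_true {y_true.shape} and y_pred {y_pred.shape} differ")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred])).tolist()
    labels = list(labels)
    k = len(labels)
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (y_true.size, k):
            raise ShapeError(
                f"scores shape {scores.shape} != ({y_true.size}, {k})"
            )

    confusion = confusion_matrix(y_true, y_pred, labels=labels)
    precision, recall, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    for i, label in enumerate(labels):
        if support[i] == 0:
            logger.warning("class %r has zero support; recall reported as 0", label)

    aucs: list = []
    for i, label in enumerate(labels):
        if scores is None:
            aucs.append(None)
            continue
        positives = (y_true == label).astype(int)
        if positives.sum() == 0 or positives.sum() == positives.size:
            logger.warning("AUC undefined for class %r (degenerate support)", label)
            aucs.append(None)
            continue
        aucs.append(float(roc_auc_score(positives, scores[:, i])))

    per_class = {
        label: {
            "precision": float(precision[i]),
            "recall": float(recall[i]),
            "f1": float(f1[i]),
            "auc": aucs[i],
        }
        for i, label in enumerate(labels)
    }
    accuracy = float(np.trace(confusion) / max(1, confusion.sum()))
    support = support.astype(float)
    macro_avg = {
        "precision": _average(precision.tolist()),
        "recall": _average(recall.tolist()),
        "f1": _average(f1.tolist()),
        "auc": _average(aucs),
    }
    weighted_avg = {
        "precision": _average(precision.tolist(), support),
        "recall": _average(recall.tolist(), support),
        "f1": _average(f1.tolist(), support),
        "auc": _average(aucs, support),
    }
    return EvalReport(
        labels=labels,
        confusion=confusion,
        per_class=per_class,
        accuracy=accuracy,
        macro_avg=macro_avg,
        weighted_avg=weighted_avg,
    )


def write_report(report: EvalReport, path) -> None:
    """JSON at full precision plus the rendered percentage table alongside."""
    path = Path(path)
    blob = report.to_dict()
    blob["table"] = report.render_table()
    path.write_text(json.dumps(blob, indent=2))


def read_report(path) -> EvalReport:
    return EvalReport.from_dict(json.loads(Path(path).read_text()))
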