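"""Per-class evaluation metrics and confusion matrices.

Reported per class (one-vs-rest): sensitivity (recall, TP/(TP+FN)),
selectivity (specificity, TN/(TN+FP)), precision, and F1.  Because the
field's usage of "selectivity" is ambiguous, precision is always reported
alongside it.  Undefined ratios (zero denominator) are reported as 0.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix


def _safe_div(num: float, den: float) -> float:
    return float(num / den) if den else 0.0


@dataclass
class EvaluationReport:
    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true class, columns = predicted
    per_class: dict[str, dict[str, float]]
    overall_accuracy: float

    @classmethod
    def from_confusion(cls, confusion, classes: Sequence[str]) -> "EvaluationReport":
        conf = np.asarray(confusion, dtype=float)
        total = conf.sum()
        per_class: dict[str, dict[str, float]] = {}
        for i, name in enumerate(classes):
            tp = conf[i, i]
            fn = conf[i, :].sum() - tp
            fp = conf[:, i].sum() - tp
            tn = total - tp - fn - fp
            sens = _safe_div(tp, tp + fn)
            prec = _safe_div(tp, tp + fp)
            per_class[name] = {
                "sensitivity": sens,
                "selectivity": _safe_div(tn, tn + fp),
                "precision": prec,
                "f1": _safe_div(2 * prec * sens, prec + sens),
                "support": float(tp + fn),
            }
        return cls(
            classes=tuple(classes),
            confusion=conf,
            per_class=per_class,
            overall_accuracy=_safe_div(np.trace(conf), total),
        )

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] | None = None
    ) -> "EvaluationReport":
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        unknown = set(y_true) - set(classes)
        if unknown:
            raise ValueError(f"test classes absent from the model: {sorted(unknown)}")
        conf = confusion_matrix(list(y_true), list(y_pred), labels=list(classes))
        return cls.from_confusion(conf, classes)

    @property
    def normalized_confusion(self) -> np.ndarray:
        """Row-normalized confusion matrix (rows sum to 1 where populated)."""
        row_sums = self.confusion.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(row_sums > 0, self.confusion / row_sums, 0.0)
        return norm

    @property
    def macro_f1(self) -> float:
        return float(np.mean([m["f1"] for m in self.per_class.values()]))

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "normalized_confusion": self.normalized_confusion.tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "macro_f1": self.macro_f1,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        pd.DataFrame(self.confusion, index=list(self.classes), columns=list(self.classes)).to_csv(
            path.with_suffix(".confusion.csv")
        )
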