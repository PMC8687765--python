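"""Five-class confusion matrix and per-class Se / Sp / +p / Acc.

For each class the one-vs-rest counts are read off the 5x5 confusion matrix
(rows = reference labels, columns = predictions, order N, S, V, F, Q):
TP is the diagonal cell, FN the rest of the row, FP the rest of the column,
TN everything else.  The four rates are

    Se  = TP / (TP + FN)        sensitivity (recall)
    Sp  = TN / (TN + FP)        specificity
    +p  = TP / (TP + FP)        positive predictive value
    Acc = (TP + TN) / total     per-class accuracy

reported as percentages.  A zero denominator yields NaN (undefined-marked),
never a division error; overall accuracy is trace / total.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .aami import CLASS_NAMES, N_CLASSES, as_class

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix5",
    "ClassMetrics",
    "confusion_matrix",
    "per_class_counts",
    "metrics",
    "report_frame",
    "plot_confusion",
]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix5:
    counts: np.ndarray  # (5, 5) ints; rows true, columns predicted

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValueError("counts must be a nonnegative 5x5 matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        """Percentage of beats on the diagonal."""
        return 100.0 * float(np.trace(self.counts)) / self.total


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    se: float
    sp: float
    ppv: float
    acc: float


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix5:
    """Count matrix with ``counts[i, j] = #(true == i, predicted == j)``."""
    yt = [as_class(v) for v in true_labels]
    yp = [as_class(v) for v in predicted_labels]
    if len(yt) != len(yp):
        raise ValueError("true and predicted label lists differ in length")
    counts = _sk_confusion(yt, yp, labels=list(range(N_CLASSES)))
    return ConfusionMatrix5(counts=counts)


def per_class_counts(cm: ConfusionMatrix5, cls) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, TN, FN) for ``cls``."""
    i = int(as_class(cls))
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i, :].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return tp, fp, tn, fn


def _rate(num: int, den: int, what: str, cls: str) -> float:
    if den == 0:
        logger.warning("%s undefined for class %s (zero denominator)", what, cls)
        return math.nan
    return 100.0 * num / den


def metrics(cm: ConfusionMatrix5) -> dict:
    """Per-class ClassMetrics keyed by class name, plus ``'overall_accuracy'``."""
    out: dict = {}
    for name in CLASS_NAMES:
        tp, fp, tn, fn = per_class_counts(cm, name)
        out[name] = ClassMetrics(
            tp=tp, fp=fp, tn=tn, fn=fn,
            se=_rate(tp, tp + fn, "Se", name),
            sp=_rate(tn, tn + fp, "Sp", name),
            ppv=_rate(tp, tp + fp, "+p", name),
            acc=_rate(tp + tn, cm.total, "Acc", name),
        )
    out["overall_accuracy"] = cm.overall_accuracy
    return out


def report_frame(result: dict, ndigits: int = 2) -> pd.DataFrame:
    """Reporting-layer table (percentages rounded only here)."""
    rows = []
    for name in CLASS_NAMES:
        m = result[name]
        rows.append({
            "class": name, "TP": m.tp, "FP": m.fp, "TN": m.tn, "FN": m.fn,
            "Se%": round(m.se, ndigits), "Sp%": round(m.sp, ndigits),
            "+p%": round(m.ppv, ndigits), "Acc%": round(m.acc, ndigits),
        })
    return pd.DataFrame(rows)


def plot_confusion(cm: ConfusionMatrix5, path) -> None:
    """Write a heatmap of the confusion matrix to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(N_CLASSES), CLASS_NAMES)
    ax.set_yticks(range(N_CLASSES), CLASS_NAMES)
    ax.set_xlabel("Predicted label")
    ax.set_ylabel("Reference label")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="black", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
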