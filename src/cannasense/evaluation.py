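"""Confusion-matrix evaluation: per-class and macro metrics, accuracy, AUC.

Conventions: confusion-matrix rows are actual and columns predicted, in
fixed class order (N, L, MI).  Per-class precision is TP over the column
sum, recall TP over the row sum, F1 their harmonic mean; macro metrics are
unweighted means over the three classes.  A class never predicted has
undefined precision — it is reported as NaN, dropped from the macro mean,
and noted in the audit.  AUC is one-vs-rest per class, macro-averaged.
Rounding (2 decimals) happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .labeling import CLASS_ORDER


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # (3, 3) ints, rows = actual
    class_order: tuple = CLASS_ORDER

    def __post_init__(self):
        m = np.asarray(self.counts)
        k = len(self.class_order)
        if m.shape != (k, k) or (m < 0).any() or not np.issubdtype(m.dtype, np.integer):
            raise ValueError(f"confusion matrix must be {k}x{k} nonnegative integers")
        self.counts = m

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


@dataclass
class EvalReport:
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    auc: dict[str, float] = field(default_factory=dict)
    macro_auc: float = np.nan
    audit: list[str] = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> "EvalReport":
        """Report-time rounding; computation keeps full precision."""
        r = lambda v: (np.nan if v is None or np.isnan(v)
                       else round(float(v), ndigits))
        return EvalReport(
            precision={k: r(v) for k, v in self.precision.items()},
            recall={k: r(v) for k, v in self.recall.items()},
            f1={k: r(v) for k, v in self.f1.items()},
            macro_precision=r(self.macro_precision),
            macro_recall=r(self.macro_recall),
            macro_f1=r(self.macro_f1),
            accuracy=r(self.accuracy),
            auc={k: r(v) for k, v in self.auc.items()},
            macro_auc=r(self.macro_auc),
            audit=list(self.audit),
        )


def confusion(y_true, y_pred, class_order=CLASS_ORDER) -> ConfusionMatrix:
    lut = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    m = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        m[lut[t], lut[p]] += 1
    return ConfusionMatrix(m, class_order)


def metrics_from_confusion(matrix: ConfusionMatrix) -> EvalReport:
    """Exact function of the matrix — no model or scores required."""
    m = matrix.counts.astype(float)
    classes = matrix.class_order
    tp = np.diag(m)
    col = m.sum(axis=0)
    row = m.sum(axis=1)
    audit: list[str] = []
    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(classes):
        if col[i] == 0:
            precision[c] = np.nan
            audit.append(f"precision undefined for class {c} "
                         "(never predicted); excluded from macro")
        else:
            precision[c] = tp[i] / col[i]
        recall[c] = tp[i] / row[i] if row[i] > 0 else np.nan
        if row[i] == 0:
            audit.append(f"recall undefined for class {c} (no support); "
                         "excluded from macro")
        p, r = precision[c], recall[c]
        if np.isnan(p) or np.isnan(r):
            f1[c] = np.nan
        else:
            f1[c] = 0.0 if p + r == 0 else 2 * p * r / (p + r)

    macro = lambda d: float(np.nanmean(list(d.values())))
    return EvalReport(
        precision=precision, recall=recall, f1=f1,
        macro_precision=macro(precision), macro_recall=macro(recall),
        macro_f1=macro(f1),
        accuracy=float(tp.sum() / m.sum()),
        audit=audit,
    )


def roc_auc_ovr(y_true, scores, class_order=CLASS_ORDER
                ) -> tuple[dict[str, float], float]:
    """One-vs-rest AUC per class (rank statistic) and their macro mean.

    Classes absent from ``y_true`` get NaN and are excluded from the macro.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    aucs: dict[str, float] = {}
    for i, c in enumerate(class_order):
        pos = y == c
        if pos.all() or not pos.any():
            aucs[c] = np.nan
            continue
        aucs[c] = float(roc_auc_score(pos.astype(int), s[:, i]))
    return aucs, float(np.nanmean(list(aucs.values())))


def evaluate(model, X_test, y_test) -> tuple[ConfusionMatrix, EvalReport]:
    """Score a trained model on held-out windows."""
    y_pred = model.predict(X_test)
    cm = confusion(y_test, y_pred, model.class_order)
    report = metrics_from_confusion(cm)
    proba = model.predict_proba(X_test)
    report.auc, report.macro_auc = roc_auc_ovr(y_test, proba,
                                               model.class_order)
    return cm, report
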