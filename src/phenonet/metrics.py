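"""Classification and regression performance metrics.

Classification metrics are computed one-vs-rest from a K x K confusion
matrix (rows = actual, columns = predicted):

* accuracy        = (TP + TN) / n
* sensitivity     = TP / (TP + FN)                  (= recall)
* specificity_eq3 = TP / (TP + FP)

  This quantity is a *precision*, but it is kept under this name because
  the evaluation protocol this package mirrors defines "specificity" with
  exactly this formula.  It is aliased as ``precision``, and the
  conventional specificity TN / (TN + FP) is exposed separately as
  ``specificity_standard``.

* FPR             = FP / (FP + TN)
* F1              = harmonic mean of sensitivity and precision

Zero-denominator cases return 0.0 with a warning, so downstream reports
stay deterministic instead of propagating NaN.

Regression metrics for growth-day prediction:

* RMSE = sqrt(mean((yhat - y)^2))
* R^2  = 1 - SSE / SST,  SST about the mean of the true days
* RPD  = population SD of the true days / RMSE

together with per-day residual groups (the data behind day-wise boxplots).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "ClassMetrics",
    "ClassificationReport",
    "RegressionReport",
    "confusion_matrix",
    "one_vs_rest_counts",
    "classification_metrics",
    "macro_report",
    "rmse",
    "r_squared",
    "rpd",
    "residuals_by_day",
    "regression_report",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # (K, K) ints; rows = actual, cols = predicted
    class_names: List[str]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def micro_accuracy(self) -> float:
        n = self.n
        return float(np.trace(self.counts) / n) if n else 0.0


@dataclass
class BinaryCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassMetrics:
    accuracy: float
    sensitivity: float
    specificity_eq3: float   # TP / (TP + FP), see module docstring
    fpr: float
    f1: float
    specificity_standard: float  # TN / (TN + FP)

    @property
    def precision(self) -> float:
        return self.specificity_eq3


@dataclass
class ClassificationReport:
    per_class: Dict[str, ClassMetrics]
    macro_accuracy: float
    macro_sensitivity: float
    macro_specificity_eq3: float
    macro_fpr: float
    macro_f1: float
    overall_accuracy: float  # trace / n
    n: int

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "macro_accuracy": self.macro_accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity_eq3": self.macro_specificity_eq3,
            "macro_fpr": self.macro_fpr,
            "macro_f1": self.macro_f1,
            "n": self.n,
            "per_class": {k: vars(v) for k, v in self.per_class.items()},
        }


@dataclass
class RegressionReport:
    rmse: float
    r2: float
    rpd: float
    residuals_by_day: Dict[int, List[float]] = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "rpd": self.rpd, "n": self.n}


# ---------------------------------------------------------------------------
# classification


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     class_names: Sequence[str]) -> ConfusionMatrix:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label {t!r}/{p!r} not in class_names")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_names))


def one_vs_rest_counts(cm: ConfusionMatrix, k: int) -> BinaryCounts:
    counts = cm.counts
    if not 0 <= k < counts.shape[0]:
        raise IndexError(f"class index {k} out of range")
    tp = int(counts[k, k])
    fn = int(counts[k, :].sum() - tp)
    fp = int(counts[:, k].sum() - tp)
    tn = int(counts.sum() - tp - fn - fp)
    return BinaryCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; returning 0.0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(bc: BinaryCounts) -> ClassMetrics:
    if bc.n == 0:
        raise ValueError("no samples")
    sens = _ratio(bc.tp, bc.tp + bc.fn, "sensitivity")
    prec = _ratio(bc.tp, bc.tp + bc.fp, "specificity_eq3/precision")
    return ClassMetrics(
        accuracy=(bc.tp + bc.tn) / bc.n,
        sensitivity=sens,
        specificity_eq3=prec,
        fpr=_ratio(bc.fp, bc.fp + bc.tn, "FPR"),
        f1=_ratio(2 * sens * prec, sens + prec, "F1"),
        specificity_standard=_ratio(bc.tn, bc.tn + bc.fp, "specificity"),
    )


def macro_report(cm: ConfusionMatrix) -> ClassificationReport:
    """Per-class one-vs-rest metrics plus unweighted macro averages."""
    per_class = {
        name: classification_metrics(one_vs_rest_counts(cm, k))
        for k, name in enumerate(cm.class_names)
    }
    vals = list(per_class.values())

    def mean(attr):
        return float(np.mean([getattr(v, attr) for v in vals])) if vals else 0.0

    return ClassificationReport(
        per_class=per_class,
        macro_accuracy=mean("accuracy"),
        macro_sensitivity=mean("sensitivity"),
        macro_specificity_eq3=mean("specificity_eq3"),
        macro_fpr=mean("fpr"),
        macro_f1=mean("f1"),
        overall_accuracy=cm.micro_accuracy(),
        n=cm.n,
    )


# ---------------------------------------------------------------------------
# regression


def _check_lengths(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-d arrays of equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    y_true, y_pred = _check_lengths(y_true, y_pred)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r_squared(y_true, y_pred) -> float:
    y_true, y_pred = _check_lengths(y_true, y_pred)
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant y_true")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - sse / sst


def rpd(y_true, y_pred) -> float:
    """Residual prediction deviation: population SD of true values / RMSE."""
    y_true, y_pred = _check_lengths(y_true, y_pred)
    sd = float(np.sqrt(np.mean((y_true - y_true.mean()) ** 2)))
    if sd == 0:
        raise ValueError("RPD undefined for constant y_true")
    e = rmse(y_true, y_pred)
    return math.inf if e == 0 else sd / e


def residuals_by_day(y_true, y_pred) -> Dict[int, List[float]]:
    """Residuals (yhat - y) grouped by true day; the data behind boxplots."""
    y_true, y_pred = _check_lengths(y_true, y_pred)
    out: Dict[int, List[float]] = {}
    for t, p in zip(y_true, y_pred):
        out.setdefault(int(t), []).append(float(p - t))
    return out


def regression_report(y_true, y_pred) -> RegressionReport:
    y_true, y_pred = _check_lengths(y_true, y_pred)
    return RegressionReport(
        rmse=rmse(y_true, y_pred),
        r2=r_squared(y_true, y_pred),
        rpd=rpd(y_true, y_pred),
        residuals_by_day=residuals_by_day(y_true, y_pred),
        n=int(y_true.size),
    )


# ---------------------------------------------------------------------------
# serialisation helpers


def confusion_matrix_to_csv(cm: ConfusionMatrix, path) -> None:
    """Rows = actual classes, columns = predicted classes."""
    import pandas as pd

    pd.DataFrame(cm.counts, index=cm.class_names,
                 columns=cm.class_names).to_csv(path, index_label="actual")


def report_to_json(report, path) -> None:
    """Serialise a ClassificationReport or RegressionReport to JSON."""
    import json

    from pathlib import Path

    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def report_to_csv(report: ClassificationReport, path) -> None:
    """Per-class metric table as tidy CSV (one row per class)."""
    import pandas as pd

    rows = [{"class": name, **vars(m)} for name, m in report.per_class.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def residuals_to_csv(groups: Dict[int, List[float]], path) -> None:
    """Tidy boxplot data: one (day, residual) pair per row."""
    import pandas as pd

    rows = [{"day": d, "residual": r}
            for d in sorted(groups) for r in groups[d]]
    pd.DataFrame(rows, columns=["day", "residual"]).to_csv(path, index=False)
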