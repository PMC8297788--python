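"""Confusion matrices, the six standard classification metrics, and
inter-cycle interval summaries.

Metrics follow the usual epidemiological definitions: sensitivity
Se = TP/(TP+FN), specificity Sp = TN/(TN+FP), positive predictive value
PPV = TP/(TP+FP), negative predictive value NPV = TN/(TN+FN),
F1 = 2*PPV*Se/(PPV+Se) and accuracy Acc = (TP+TN)/total.  A metric whose
denominator is zero is reported as undefined (NaN), never silently as 0 or
1, so degenerate validation folds cannot distort aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "PerformanceMetrics",
    "IntervalSummary",
    "confusion",
    "metrics",
    "interval_summary",
    "metrics_frame",
    "format_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ["Se", "Sp", "PPV", "NPV", "F1", "Acc"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one point")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """The six derived metrics; NaN marks an undefined (0/0) value."""

    Se: float
    Sp: float
    PPV: float
    NPV: float
    F1: float
    Acc: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) if math.isfinite(v) else v
                for k, v in self.as_dict().items()}


def confusion(pred, truth) -> ConfusionMatrix:
    """Tally a binary prediction series against binary truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: pred {pred.shape}, truth {truth.shape}")
    if pred.size < 1:
        raise ValueError("empty series")
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    """Se, Sp, PPV, NPV, F1 and Acc from a confusion matrix."""
    se = _ratio(cm.tp, cm.tp + cm.fn)
    sp = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    if math.isfinite(se) and math.isfinite(ppv) and (se + ppv) > 0:
        f1 = 2.0 * ppv * se / (ppv + se)
    else:
        f1 = float("nan")
    acc = _ratio(cm.tp + cm.tn, cm.total)
    return PerformanceMetrics(Se=se, Sp=sp, PPV=ppv, NPV=npv, F1=f1, Acc=acc)


@dataclass(frozen=True)
class IntervalSummary:
    """Distribution summary of inter-cycle intervals for one behavior."""

    behavior: str
    mean: float
    sd: float
    median: float
    iqr: float
    n: int


def interval_summary(gaps, behavior: str) -> IntervalSummary:
    """Sample mean, SD (n-1), median and IQR (linear-interpolated) of gaps."""
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size < 1:
        raise ValueError("interval_summary needs at least one gap")
    q25, q75 = np.percentile(gaps, [25, 75])
    return IntervalSummary(
        behavior=behavior,
        mean=float(np.mean(gaps)),
        sd=float(np.std(gaps, ddof=1)) if gaps.size > 1 else float("nan"),
        median=float(np.median(gaps)),
        iqr=float(q75 - q25),
        n=int(gaps.size),
    )


def metrics_frame(rows: list[dict]) -> pd.DataFrame:
    """Tabulate labeled confusion counts + metrics in the standard column
    order (TP, FP, TN, FN, Se, Sp, PPV, NPV, F1, Acc)."""
    cols = ["name", "TP", "FP", "TN", "FN", *METRIC_COLUMNS]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    return out.reindex(columns=[c for c in cols if c in out.columns])


def format_table(df: pd.DataFrame) -> str:
    """Plain-text table with thousands separators on count columns."""
    if df.empty:
        return "\t".join(df.columns)
    shown = df.copy()
    for col in ("TP", "FP", "TN", "FN"):
        if col in shown.columns:
            shown[col] = shown[col].map(
                lambda v: f"{int(v):,}" if pd.notna(v) else ""
            )
    for col in shown.columns:
        if shown[col].dtype.kind == "f":
            shown[col] = shown[col].map(
                lambda v: f"{v:.2f}" if pd.notna(v) else "undefined"
            )
    return shown.to_string(index=False)


def write_metrics_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
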