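"""Classification metrics, confusion matrices, ROC/AUC and reports.

MI is the positive class throughout. Metrics with a zero denominator are
reported as None (undefined), never silently as 0 — with only a handful of
healthy controls per fold, empty confusion cells do occur.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ConfusionMatrix", "MetricReport", "ROCCurve",
           "confusion", "metrics", "roc_auc", "cut_point", "report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with MI positive; rows actual, columns predicted."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricReport:
    """The six headline metrics as fractions in [0, 1] (None = undefined)."""

    sens: float | None
    spec: float | None
    acc: float | None
    ppv: float | None
    npv: float | None
    f1: float | None

    def as_percent(self, decimals: int = 2) -> dict:
        """Render as percentages rounded to ``decimals`` places."""
        return {k: None if v is None else round(100 * v, decimals)
                for k, v in asdict(self).items()}


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count the 2x2 confusion matrix from MI/HC label sequences."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    for arr in (y_true, y_pred):
        bad = set(arr) - {"MI", "HC"}
        if bad:
            raise ValueError(f"labels must be MI or HC, got {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == "MI") & (y_pred == "MI"))),
        fn=int(np.sum((y_true == "MI") & (y_pred == "HC"))),
        fp=int(np.sum((y_true == "HC") & (y_pred == "MI"))),
        tn=int(np.sum((y_true == "HC") & (y_pred == "HC"))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity, specificity, accuracy, PPV, NPV and f1 from counts."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return MetricReport(sens=sens, spec=spec, acc=acc, ppv=ppv, npv=npv, f1=f1)


def roc_auc(scores, y_true) -> ROCCurve:
    """ROC curve over a threshold sweep and the trapezoid-rule AUC.

    Tied scores collapse to one operating point, which makes the trapezoid
    AUC equal to the rank-statistic (Mann-Whitney) formulation with
    midpoint tie handling.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true)
    if y.dtype.kind in "OSU":
        y = (y == "MI").astype(int)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def cut_point(curve: ROCCurve, criterion: str = "youden"
              ) -> tuple[float, float, float]:
    """Operating point of a ROC curve: ``(fpr, tpr, threshold)``.

    ``youden`` maximizes J = tpr - fpr, ties broken toward higher tpr
    (sensitivity is clinically favored for MI detection);
    ``closest_topleft`` minimizes the distance to the (0, 1) corner.
    """
    if len(curve.tpr) < 2:
        raise ValueError("degenerate ROC curve")
    if criterion == "youden":
        key = curve.tpr - curve.fpr + 1e-12 * curve.tpr
        idx = int(np.argmax(key))
        # exact-tie sweep toward higher tpr
        j = curve.tpr - curve.fpr
        tied = np.flatnonzero(j == j[idx])
        idx = tied[np.argmax(curve.tpr[tied])]
    elif criterion == "closest_topleft":
        idx = int(np.argmin(curve.fpr ** 2 + (1 - curve.tpr) ** 2))
    else:
        raise ValueError(f"unknown cut-point criterion {criterion!r}")
    return float(curve.fpr[idx]), float(curve.tpr[idx]), float(curve.thresholds[idx])


def report(entries: list[dict], out_json: str | Path | None = None,
           out_csv: str | Path | None = None) -> str:
    """Serialize per-model metric entries as canonical JSON (+ CSV summary).

    Each entry is a dict with at least a ``model`` key; remaining keys
    (metrics, auc, fold accuracies, confusion counts, ...) are written
    as-is. Entries are sorted by model name and serialized with sorted
    keys, so identical inputs produce byte-identical output.
    """
    entries = sorted(entries, key=lambda e: str(e.get("model", "")))

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, np.ndarray)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and np.isnan(obj):
            return None
        return obj

    payload = json.dumps(_clean(entries), indent=1, sort_keys=True)
    if out_json is not None:
        Path(out_json).write_text(payload)
    if out_csv is not None:
        flat = []
        for e in entries:
            row = {"model": e.get("model", "")}
            for k, v in e.items():
                if isinstance(v, (int, float, str)) and k != "model":
                    row[k] = v
                elif isinstance(v, dict) and k == "metrics_pct":
                    row.update(v)
            flat.append(row)
        pd.DataFrame(flat).to_csv(out_csv, index=False)
    return payload
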