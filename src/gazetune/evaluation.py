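"""Multiclass evaluation: confusion counts, percentage metrics, macro AUROC /
AUPRC, and bootstrap average-precision intervals.

Per-class one-vs-rest confusion counts feed the four percentage metrics

    accuracy    = (TP + TN) / (TN + TP + FN + FP) * 100
    precision   = TP / (TP + FP) * 100
    sensitivity = TP / (TP + FN) * 100
    F1          = 2 * sensitivity * precision / (sensitivity + precision)

macro-averaged over classes. AUROC uses the rank statistic and AUPRC the
step-interpolated precision-recall area, both per class one-vs-rest and
averaged. Average precision is bootstrapped over the evaluation set to give
2.5% / 50% / 97.5% percentile quantiles, with a rank helper ordering methods
by median AP.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "macro_auc",
    "bootstrap_ap",
    "rank_methods",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class."""

    classes: list
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n: int

    def matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn},
            index=[str(c) for c in self.classes],
        )


def confusion(y_true, y_pred, classes) -> ConfusionCounts:
    """Per-class one-vs-rest confusion counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    classes = list(classes)
    known = set(classes)
    unknown = (set(np.unique(y_true)) | set(np.unique(y_pred))) - known
    if unknown:
        raise ValueError(f"labels not in classes: {sorted(map(str, unknown))}")
    n = len(y_true)
    tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in classes])
    fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in classes])
    fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in classes])
    tn = n - tp - fp - fn
    return ConfusionCounts(classes=classes, tp=tp, tn=tn, fp=fp, fn=fn, n=n)


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    nz = den > 0
    if not nz.all():
        warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
    out[nz] = num[nz] / den[nz]
    return out


@dataclass
class EvalReport:
    """Macro-averaged metrics (percent) plus ranking/uncertainty fields."""

    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    per_class: pd.DataFrame | None = None
    auroc_macro: float | None = None
    auprc_macro: float | None = None
    ap_quantiles: dict | None = None
    rank: int | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
        }
        if self.auroc_macro is not None:
            out["auroc_macro"] = self.auroc_macro
        if self.auprc_macro is not None:
            out["auprc_macro"] = self.auprc_macro
        if self.ap_quantiles is not None:
            out["ap_quantiles"] = self.ap_quantiles
            # AP on the percent scale alongside the [0, 1] scale
            out["ap_quantiles_percent"] = {
                k: 100.0 * v for k, v in self.ap_quantiles.items()
            }
        if self.rank is not None:
            out["rank"] = self.rank
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Percentage metrics from confusion counts, macro-averaged over classes."""
    if counts.n <= 0:
        raise ValueError("need at least one sample")
    tp, tn, fp, fn = (
        counts.tp.astype(float),
        counts.tn.astype(float),
        counts.fp.astype(float),
        counts.fn.astype(float),
    )
    acc = (tp + tn) / (tn + tp + fn + fp) * 100.0
    prec = _safe_ratio(tp, tp + fp, "precision") * 100.0
    sens = _safe_ratio(tp, tp + fn, "sensitivity") * 100.0
    f1 = _safe_ratio(2.0 * sens * prec, sens + prec, "F1")
    per_class = pd.DataFrame(
        {"accuracy": acc, "precision": prec, "sensitivity": sens, "f1": f1},
        index=[str(c) for c in counts.classes],
    )
    return EvalReport(
        accuracy=float(acc.mean()),
        precision=float(prec.mean()),
        sensitivity=float(sens.mean()),
        f1=float(f1.mean()),
        per_class=per_class,
    )


def macro_auc(y_true, scores: np.ndarray, classes, kind: str = "roc") -> float:
    """Macro-averaged one-vs-rest AUROC or AUPRC.

    Classes absent from ``y_true`` are skipped with a warning, so the mean is
    over the classes actually present.
    """
    if kind not in ("roc", "pr"):
        raise ValueError("kind must be 'roc' or 'pr'")
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(y_true):
        raise ValueError("score rows must align with y_true")
    vals = []
    for j, c in enumerate(classes):
        mask = y_true == c
        if mask.all() or not mask.any():
            warnings.warn(f"class {c!r} absent from y_true (or exclusive); skipped",
                          stacklevel=2)
            continue
        if kind == "roc":
            vals.append(roc_auc_score(mask.astype(int), scores[:, j]))
        else:
            vals.append(average_precision_score(mask.astype(int), scores[:, j]))
    if not vals:
        raise ValueError("no class had both positive and negative samples")
    return float(np.mean(vals))


def bootstrap_ap(
    y_true,
    scores: np.ndarray,
    classes,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Percentile bootstrap of macro average precision.

    Returns ``{0.025: q_lo, 0.5: q_med, 0.975: q_hi}``. Resamples that
    collapse to a single class are redrawn up to 10 times.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n = len(y_true)
    rng = np.random.default_rng(seed)
    aps = np.empty(B)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(B):
            for _ in range(10):
                idx = rng.integers(0, n, size=n)
                if len(np.unique(y_true[idx])) >= 2:
                    break
            aps[b] = macro_auc(y_true[idx], scores[idx], classes, kind="pr")
    q = np.quantile(aps, [0.025, 0.5, 0.975])
    return {0.025: float(q[0]), 0.5: float(q[1]), 0.975: float(q[2])}


def rank_methods(median_ap: dict) -> dict:
    """Rank methods by descending median AP (1 = best)."""
    order = sorted(median_ap, key=lambda k: -median_ap[k])
    return {name: r + 1 for r, name in enumerate(order)}
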