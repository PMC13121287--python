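"""Evaluation statistics: confusion-matrix metrics, McNemar's paired test,
overlap scores, per-artery detection metrics and risk-category confusion.

All metrics are kept at full precision internally; ``round2`` / the text
report round to two decimals only at the reporting layer.  Metrics whose
denominator is zero are returned as NaN and rendered as "n/a", never
silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ct_io import ARTERY_NAMES

RISK_ORDER = ("low", "moderate", "high", "very_high")

#: discordant-pair count at which McNemar switches from the exact binomial
#: test to the continuity-corrected chi-square approximation
MCNEMAR_EXACT_LIMIT = 25


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 confusion matrix for the calcified-slice classification task."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tn + self.fp + self.fn + self.tp == 0:
            raise ValueError("confusion matrix is empty")

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionMatrix2":
        t = np.asarray(y_true).astype(int)
        p = np.asarray(y_pred).astype(int)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred must be the same length")
        return ConfusionMatrix2(tn=int(((t == 0) & (p == 0)).sum()),
                                fp=int(((t == 0) & (p == 1)).sum()),
                                fn=int(((t == 1) & (p == 0)).sum()),
                                tp=int(((t == 1) & (p == 1)).sum()))


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else float("nan")


def binary_metrics(cm: ConfusionMatrix2) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and per-class precision/recall/F1."""
    tn, fp, fn, tp = cm.tn, cm.fp, cm.fn, cm.tp
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec1 = _safe_div(tp, tp + fp)
    prec0 = _safe_div(tn, tn + fn)
    rec1 = sens
    rec0 = spec
    f1_1 = _safe_div(2 * prec1 * rec1, prec1 + rec1)
    f1_0 = _safe_div(2 * prec0 * rec0, prec0 + rec0)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": _safe_div(tp + tn, tn + fp + fn + tp),
        "precision_class0": prec0,
        "recall_class0": rec0,
        "f1_class0": f1_0,
        "precision_class1": prec1,
        "recall_class1": rec1,
        "f1_class1": f1_1,
    }


def round2(metrics: dict[str, float]) -> dict[str, float | str]:
    """Reporting-layer rounding to 2 decimals; NaN becomes 'n/a'."""
    out: dict[str, float | str] = {}
    for k, v in metrics.items():
        out[k] = "n/a" if (isinstance(v, float) and np.isnan(v)) else round(float(v), 2)
    return out


def reduction_percent(before: int | float, after: int | float) -> float:
    """Percentage reduction 100*(before-after)/before."""
    if before <= 0:
        raise ValueError("'before' count must be positive")
    return 100.0 * (before - after) / before


def mcnemar_test(y_true, pred_a, pred_b) -> dict[str, float | bool]:
    """McNemar's paired test comparing two classifiers on the same items.

    Discordant counts: b = A correct & B wrong, c = A wrong & B correct.
    Uses the exact binomial test when b + c < 25, otherwise the
    continuity-corrected chi-square approximation.
    """
    t = np.asarray(y_true).astype(int)
    a = np.asarray(pred_a).astype(int)
    bb = np.asarray(pred_b).astype(int)
    if not (t.shape == a.shape == bb.shape):
        raise ValueError("all three prediction arrays must align")
    a_ok = a == t
    b_ok = bb == t
    b_count = int((a_ok & ~b_ok).sum())
    c_count = int((~a_ok & b_ok).sum())
    n = b_count + c_count
    if n == 0:
        return {"b": 0, "c": 0, "statistic": 0.0, "p_value": 1.0,
                "exact": True, "degenerate": True}
    if n < MCNEMAR_EXACT_LIMIT:
        k = min(b_count, c_count)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return {"b": b_count, "c": c_count, "statistic": float(k), "p_value": p,
                "exact": True, "degenerate": False}
    statistic = (abs(b_count - c_count) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return {"b": b_count, "c": c_count, "statistic": statistic, "p_value": p,
            "exact": False, "degenerate": False}


def iou_dice(pred_mask: np.ndarray, true_mask: np.ndarray,
             classes: tuple[int, ...] = (1, 2, 3, 4)) -> dict[int, dict[str, float]]:
    """Per-class IoU and Dice.

    A class absent from both masks yields NaN for both metrics and is
    excluded from any averaging done by the caller.
    """
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError("mask shapes differ")
    out: dict[int, dict[str, float]] = {}
    for c in classes:
        p = pred == c
        t = true == c
        inter = float((p & t).sum())
        union = float((p | t).sum())
        psum = float(p.sum())
        tsum = float(t.sum())
        if union == 0:
            out[c] = {"iou": float("nan"), "dice": float("nan")}
        else:
            out[c] = {"iou": inter / union, "dice": 2 * inter / (psum + tsum)}
    return out


def artery_detection_metrics(pred_masks: list[np.ndarray],
                             true_masks: list[np.ndarray]) -> dict[str, dict[str, float]]:
    """Patient-level detection metrics per artery class.

    A patient counts positive for an artery if any pixel of that class is
    present in their mask; precision/recall/F1 are tallied per artery over
    patients.
    """
    if len(pred_masks) != len(true_masks):
        raise ValueError("need one predicted mask per true mask")
    out: dict[str, dict[str, float]] = {}
    for cls, name in enumerate(ARTERY_NAMES, start=1):
        tp = fp = fn = tn = 0
        for p, t in zip(pred_masks, true_masks):
            has_p = bool((np.asarray(p) == cls).any())
            has_t = bool((np.asarray(t) == cls).any())
            tp += has_p and has_t
            fp += has_p and not has_t
            fn += has_t and not has_p
            tn += not has_p and not has_t
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        out[name] = {"precision": prec, "recall": rec,
                     "f1": _safe_div(2 * prec * rec, prec + rec),
                     "support": tp + fn}
    return out


def risk_confusion(pred_risks: list[str], true_risks: list[str]) -> dict:
    """4x4 risk-category confusion with per-category one-vs-rest metrics.

    Returns the matrix (rows = truth, cols = prediction, ordered low ->
    very_high), per-category precision/recall/F1/sensitivity/specificity,
    and support-weighted averages.  Sensitivity equals recall and is listed
    under both names (standard one-vs-rest definitions).
    """
    if len(pred_risks) == 0:
        raise ValueError("empty risk lists")
    if len(pred_risks) != len(true_risks):
        raise ValueError("prediction and truth lists must align")
    idx = {c: i for i, c in enumerate(RISK_ORDER)}
    mat = np.zeros((4, 4), dtype=int)
    for p, t in zip(pred_risks, true_risks):
        mat[idx[t], idx[p]] += 1
    n = mat.sum()
    per_cat: dict[str, dict[str, float]] = {}
    for c, i in idx.items():
        tp = mat[i, i]
        fn = mat[i].sum() - tp
        fp = mat[:, i].sum() - tp
        tn = n - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        per_cat[c] = {
            "precision": prec,
            "recall": rec,
            "f1": _safe_div(2 * prec * rec, prec + rec),
            "sensitivity": rec,
            "specificity": _safe_div(tn, tn + fp),
            "support": int(tp + fn),
        }
    supports = np.array([per_cat[c]["support"] for c in RISK_ORDER], dtype=float)
    weighted = {}
    for m in ("precision", "recall", "f1"):
        vals = np.array([per_cat[c][m] for c in RISK_ORDER])
        ok = ~np.isnan(vals) & (supports > 0)
        weighted[m] = float((vals[ok] * supports[ok]).sum() / supports[ok].sum())
    return {
        "matrix": mat,
        "order": RISK_ORDER,
        "per_category": per_cat,
        "accuracy": float(np.trace(mat) / n),
        "weighted_avg": weighted,
    }


def format_binary_report(name_a: str, metrics_a: dict, name_b: str, metrics_b: dict) -> str:
    """Two-column human-readable comparison of binary classification metrics."""
    ra, rb = round2(metrics_a), round2(metrics_b)
    lines = [f"{'metric':<20} {name_a:>14} {name_b:>14}"]
    for k in ra:
        lines.append(f"{k:<20} {str(ra[k]):>14} {str(rb[k]):>14}")
    return "\n".join(lines)
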