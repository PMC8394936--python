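"""Evaluation of point predictions against expert annotations.

Predicted centroids are paired with annotated centroids by greedy
nearest-first matching inside a radius; unmatched predictions and unmatched
annotations are *background* events (a spurious detection, a missed
cilium).  From the matching the module derives

* one-vs-rest confusion counts and accuracy / precision / sensitivity /
  specificity per class and overall (percent, two decimals, half-up);
* Cohen's kappa on the label-vs-label confusion matrix, with the background
  class either included as a fourth label or excluded;
* precision/recall and F1 as functions of the score threshold, and the
  threshold maximising F1;
* angle-error statistics between automatically measured and manually
  corrected angles: MAE and SD of the axial absolute errors, the fraction
  within 5 degrees, the mean absolute percent error, and a two-sided
  Wilcoxon signed-rank test of pairwise similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .angles import axial_difference
from .synth import CLASS_NAMES

BACKGROUND_LABEL = "background"
ALL_LABELS = CLASS_NAMES + (BACKGROUND_LABEL,)

__all__ = [
    "BACKGROUND_LABEL",
    "Matching",
    "ConfusionCounts",
    "MetricsReport",
    "AngleErrorStats",
    "match_points",
    "confusion_counts",
    "classification_metrics",
    "confusion_matrix_from_matching",
    "cohen_kappa",
    "pr_f1_curves",
    "angle_error_stats",
    "round_half_up",
]


def _xy(obj):
    if hasattr(obj, "centroid"):
        return obj.centroid
    if hasattr(obj, "x"):
        return (obj.x, obj.y)
    return (obj[0], obj[1])


def _label(obj):
    if hasattr(obj, "class_label"):
        return obj.class_label
    if hasattr(obj, "cls"):
        return obj.cls
    return obj[2]


@dataclass
class Matching:
    """Greedy pairing of predictions and annotations.

    ``pairs`` holds (pred_index, truth_index, distance); the label lists are
    aligned with the original inputs.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_pred: list[int]
    unmatched_truth: list[int]
    pred_labels: list[str]
    truth_labels: list[str]


def match_points(predicted, annotated, radius: float) -> Matching:
    """Match predicted to annotated points, nearest pairs first.

    Each point is used at most once; pairs farther apart than ``radius``
    stay unmatched.  Inputs may be :class:`~ciliaquant.detection.Detection`
    objects, annotation records with ``.x``/``.y``/``.cls``, or
    (x, y, class) triples.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    pred_xy = np.array([_xy(p) for p in predicted], dtype=float).reshape(-1, 2)
    true_xy = np.array([_xy(a) for a in annotated], dtype=float).reshape(-1, 2)
    pred_labels = [_label(p) for p in predicted]
    truth_labels = [_label(a) for a in annotated]

    pairs: list[tuple[int, int, float]] = []
    used_p: set[int] = set()
    used_t: set[int] = set()
    if len(predicted) and len(annotated):
        d = cdist(pred_xy, true_xy)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            dist = d[i, j]
            if dist > radius:
                break
            if i in used_p or j in used_t:
                continue
            pairs.append((int(i), int(j), float(dist)))
            used_p.add(int(i))
            used_t.add(int(j))
    return Matching(
        pairs=pairs,
        unmatched_pred=[i for i in range(len(predicted)) if i not in used_p],
        unmatched_truth=[j for j in range(len(annotated)) if j not in used_t],
        pred_labels=pred_labels,
        truth_labels=truth_labels,
    )


# ---------------------------------------------------------------------------
# one-vs-rest confusion counts and metrics

@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/TN/FN tallies plus their element-wise sum.

    Events are the matched pairs plus every unmatched point.  For class c a
    matched pair counts as TP_c (both labels c), FP_c (predicted c, truth
    differs), FN_c (truth c, prediction differs) or TN_c; an unmatched
    prediction of class c is FP_c, an unmatched annotation of class c is
    FN_c, and both are TN for every other class.
    """

    per_class: dict[str, dict[str, int]]

    @property
    def overall(self) -> dict[str, int]:
        return {k: sum(self.per_class[c][k] for c in self.per_class)
                for k in ("tp", "fp", "tn", "fn")}

    def as_frame(self) -> pd.DataFrame:
        rows = {c: self.per_class[c] for c in self.per_class}
        rows["overall"] = self.overall
        return pd.DataFrame(rows).T[["tp", "fp", "tn", "fn"]]


def confusion_counts(matching: Matching) -> ConfusionCounts:
    events: list[tuple[str, str]] = []  # (true label, predicted label)
    for i, j, _ in matching.pairs:
        events.append((matching.truth_labels[j], matching.pred_labels[i]))
    for i in matching.unmatched_pred:
        events.append((BACKGROUND_LABEL, matching.pred_labels[i]))
    for j in matching.unmatched_truth:
        events.append((matching.truth_labels[j], BACKGROUND_LABEL))

    per_class = {}
    for c in CLASS_NAMES:
        tp = sum(1 for t, p in events if t == c and p == c)
        fp = sum(1 for t, p in events if t != c and p == c)
        fn = sum(1 for t, p in events if t == c and p != c)
        tn = len(events) - tp - fp - fn
        per_class[c] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return ConfusionCounts(per_class=per_class)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (as in printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    def pct(num, den):
        return round_half_up(100.0 * num / den) if den > 0 else math.nan

    return {
        "accuracy": pct(tp + tn, tp + fp + tn + fn),
        "precision": pct(tp, tp + fp),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
    }


@dataclass
class MetricsReport:
    """Percent metrics per class and overall (NaN marks an undefined metric
    with a zero denominator)."""

    table: pd.DataFrame           # rows: classes + overall; columns: metrics
    counts: ConfusionCounts

    def __getitem__(self, row: str) -> dict[str, float]:
        return self.table.loc[row].to_dict()


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy/precision/sensitivity/specificity in percent, 2 decimals.

    accuracy = (TP+TN)/(TP+FP+TN+FN), precision = TP/(TP+FP),
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """
    rows = {}
    for c in counts.per_class:
        rows[c] = _metrics_from_counts(**counts.per_class[c])
    rows["overall"] = _metrics_from_counts(**counts.overall)
    table = pd.DataFrame(rows).T[
        ["accuracy", "precision", "sensitivity", "specificity"]]
    return MetricsReport(table=table, counts=counts)


# ---------------------------------------------------------------------------
# Cohen's kappa

def confusion_matrix_from_matching(matching: Matching) -> pd.DataFrame:
    """Label-vs-label counts (rows: truth, columns: prediction), with
    unmatched events filed under the ``background`` label."""
    m = pd.DataFrame(0, index=list(ALL_LABELS), columns=list(ALL_LABELS))
    for i, j, _ in matching.pairs:
        m.loc[matching.truth_labels[j], matching.pred_labels[i]] += 1
    for i in matching.unmatched_pred:
        m.loc[BACKGROUND_LABEL, matching.pred_labels[i]] += 1
    for j in matching.unmatched_truth:
        m.loc[matching.truth_labels[j], BACKGROUND_LABEL] += 1
    return m


def cohen_kappa(confusion_matrix, include_background: bool = True) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``confusion_matrix`` is a square label-vs-label table (rows: truth,
    columns: prediction).  With ``include_background=False`` the row and
    column labelled ``background`` (or, for a plain array, the last
    row/column) are dropped first.  Returns NaN when p_e = 1 (degenerate
    single-label data).
    """
    if isinstance(confusion_matrix, pd.DataFrame):
        m = confusion_matrix
        if not include_background and BACKGROUND_LABEL in m.index:
            m = m.drop(index=BACKGROUND_LABEL, columns=BACKGROUND_LABEL)
        arr = m.to_numpy(dtype=float)
    else:
        arr = np.asarray(confusion_matrix, dtype=float)
        if not include_background:
            arr = arr[:-1, :-1]
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = arr.sum()
    if n == 0:
        return math.nan
    po = np.trace(arr) / n
    pe = float((arr.sum(axis=1) * arr.sum(axis=0)).sum()) / (n * n)
    if abs(1.0 - pe) < 1e-12:
        return math.nan
    return float((po - pe) / (1.0 - pe))


# ---------------------------------------------------------------------------
# threshold curves

def pr_f1_curves(predicted, annotated, radius: float,
                 thresholds=None) -> tuple[pd.DataFrame, float]:
    """Class-averaged precision/recall/F1 at each score threshold.

    At each threshold the predictions with score >= threshold are re-matched
    to the annotations and per-class precision and recall are macro-averaged
    over the classes present in the ground truth; F1 = 2PR/(P+R).  Returns
    the curve table and the threshold with the highest F1 (smallest such
    threshold on ties).
    """
    if len(annotated) == 0:
        raise ValueError("empty ground truth")
    if thresholds is None:
        thresholds = np.round(np.linspace(0.0, 1.0, 21), 3)
    truth_classes = sorted({_label(a) for a in annotated})
    rows = []
    for t in thresholds:
        kept = [p for p in predicted if p.score >= t]
        counts = confusion_counts(match_points(kept, annotated, radius))
        precs, recs = [], []
        for c in truth_classes:
            cc = counts.per_class[c]
            if cc["tp"] + cc["fp"] > 0:
                precs.append(cc["tp"] / (cc["tp"] + cc["fp"]))
            if cc["tp"] + cc["fn"] > 0:
                recs.append(cc["tp"] / (cc["tp"] + cc["fn"]))
        p = float(np.mean(precs)) if precs else 0.0
        r = float(np.mean(recs)) if recs else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        rows.append({"threshold": float(t), "precision": p, "recall": r,
                     "f1": f1})
    curve = pd.DataFrame(rows)
    best = float(curve.loc[curve["f1"].idxmax(), "threshold"])
    return curve, best


def plot_pr_f1(curve: pd.DataFrame, path=None):
    """Plot the precision-recall and F1-vs-threshold curves side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(curve["recall"], curve["precision"], marker="o")
    ax1.set_xlabel("recall")
    ax1.set_ylabel("precision")
    ax1.set_title("precision-recall")
    ax2.plot(curve["threshold"], curve["f1"], marker="o")
    ax2.set_xlabel("score threshold")
    ax2.set_ylabel("F1")
    ax2.set_title("F1 vs threshold")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# angle errors

@dataclass
class AngleErrorStats:
    mae_deg: float
    std_abs_err_deg: float
    pct_within_5deg: float
    mean_abs_pct_err: float
    wilcoxon_p: float
    n_pairs: int


def angle_error_stats(predicted_deg, corrected_deg,
                      tolerance_deg: float = 5.0) -> AngleErrorStats:
    """Errors of automatic angles against manually corrected ones.

    Pairs where either value is the -1 failure sentinel are dropped.
    Absolute errors are axial distances min(|d|, 180-|d|); the percent
    error divides each axial error by the corrected angle (pairs with a
    corrected angle of 0 are excluded from that one statistic).  The
    Wilcoxon signed-rank test (two-sided; exact for n <= 25) probes whether
    predicted and corrected angles differ systematically.
    """
    pred = np.asarray(list(predicted_deg), dtype=float)
    corr = np.asarray(list(corrected_deg), dtype=float)
    if pred.shape != corr.shape:
        raise ValueError("predicted and corrected lists differ in length")
    ok = (pred != -1.0) & (corr != -1.0)
    pred, corr = pred[ok], corr[ok]
    if pred.size == 0:
        raise ValueError("no valid angle pairs")
    err = axial_difference(pred, corr)
    mae = float(err.mean())
    std = float(err.std(ddof=1)) if err.size > 1 else 0.0
    within = float(100.0 * np.mean(err <= tolerance_deg))
    nz = corr != 0
    mape = float(100.0 * np.mean(err[nz] / corr[nz])) if nz.any() else math.nan
    if np.allclose(pred, corr):
        p = 1.0
    else:
        mode = "exact" if pred.size <= 25 else "approx"
        p = float(stats.wilcoxon(pred, corr, alternative="two-sided",
                                 method=mode).pvalue)
    return AngleErrorStats(mae_deg=mae, std_abs_err_deg=std,
                           pct_within_5deg=within, mean_abs_pct_err=mape,
                           wilcoxon_p=p, n_pairs=int(pred.size))
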