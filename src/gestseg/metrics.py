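"""Evaluation statistics: confusion matrix, one-vs-rest class metrics,
macro AUC / F1, temporal IoU, and Total Agreement.

Total Agreement extends IoU for temporal segmentation: standard IoU counts
only positive bins, so two arrays that correctly agree a class is *absent*
everywhere score 0/0.  Total Agreement adds the matched-zero bins to both
the intersection and the union,

    TA = (|a AND b| + |NOT a AND NOT b|) / (|a OR b| + |NOT a AND NOT b|),

which algebraically equals the bin-wise agreement rate (TP + TN) / N and is
1.0 when a class is absent from both prediction and annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .annotation import BACKGROUND_LABEL, GESTURE_LABELS, AnnotationTrack
from .postprocess import SegmentationResult, annotation_occupancy

Z95 = 1.959963984540054


def _as_labels(x) -> np.ndarray:
    return np.asarray(getattr(x, "labels", x), dtype=np.int64)


def confusion_matrix(pred, truth, include_none_column: bool = True) -> pd.DataFrame:
    """Row-normalized percentage confusion matrix over the 5 gesture classes.

    Rows are annotated classes, columns predicted classes; background-truth
    frames are excluded.  Frames whose prediction is background fall into a
    trailing ``none`` column (dropped if empty) so each row sums to 100.
    """
    pred, truth = _as_labels(pred), _as_labels(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    keep = truth != BACKGROUND_LABEL
    pred, truth = pred[keep], truth[keep]
    cols = list(GESTURE_LABELS) + [BACKGROUND_LABEL]
    counts = np.zeros((len(GESTURE_LABELS), len(cols)))
    for ri, t in enumerate(GESTURE_LABELS):
        row = pred[truth == t]
        for ci, p in enumerate(cols):
            counts[ri, ci] = np.sum(row == p)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    names = [f"G{c}" for c in GESTURE_LABELS] + ["none"]
    df = pd.DataFrame(np.nan_to_num(pct), columns=names,
                      index=[f"G{c}" for c in GESTURE_LABELS])
    if not include_none_column or df["none"].sum() == 0:
        df = df.drop(columns=["none"])
    return df


@dataclass
class ClassMetrics:
    """One-vs-rest frame-level metrics with 95% confidence intervals."""

    gesture_label: int
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    n: int
    undefined_sensitivity: bool = False


def _mean_ci(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=np.float64)
    if vals.size == 0:
        return float("nan"), (float("nan"), float("nan"))
    m = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return m, (m - Z95 * se, m + Z95 * se)


def class_metrics(pred, truth, gesture_label: int,
                  video_ids: Sequence | None = None) -> ClassMetrics:
    """Sensitivity, specificity, and accuracy for one gesture class.

    Counts are one-vs-rest at the prediction-unit level.  When ``video_ids``
    is given, point estimates are means of per-video values and the 95% CI
    is a normal approximation over videos; otherwise pooled counts are used
    with a Wald binomial CI.  A class absent from the truth yields an
    undefined (NaN) sensitivity, flagged.
    """
    pred, truth = _as_labels(pred), _as_labels(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")

    def rates(p, t):
        pos = t == gesture_label
        ppos = p == gesture_label
        tp = np.sum(pos & ppos)
        fn = np.sum(pos & ~ppos)
        fp = np.sum(~pos & ppos)
        tn = np.sum(~pos & ~ppos)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        acc = (tp + tn) / max(len(t), 1)
        return float(sens), float(spec), float(acc)

    if video_ids is not None:
        video_ids = np.asarray(video_ids)
        per_video = [rates(pred[video_ids == v], truth[video_ids == v])
                     for v in pd.unique(video_ids)]
        sens, s_ci = _mean_ci([r[0] for r in per_video])
        spec, p_ci = _mean_ci([r[1] for r in per_video])
        acc, a_ci = _mean_ci([r[2] for r in per_video])
    else:
        sens, spec, acc = rates(pred, truth)

        def wald(p, n):
            if not np.isfinite(p) or n == 0:
                return (float("nan"), float("nan"))
            se = np.sqrt(max(p * (1 - p), 0.0) / n)
            return (p - Z95 * se, p + Z95 * se)

        npos = int(np.sum(truth == gesture_label))
        s_ci = wald(sens, npos)
        p_ci = wald(spec, len(truth) - npos)
        a_ci = wald(acc, len(truth))
    return ClassMetrics(gesture_label=gesture_label, sensitivity=sens,
                        specificity=spec, accuracy=acc, sensitivity_ci=s_ci,
                        specificity_ci=p_ci, accuracy_ci=a_ci, n=len(truth),
                        undefined_sensitivity=not np.isfinite(sens))


def macro_auc(probs: np.ndarray, truth, return_per_class: bool = False):
    """Macro one-vs-rest ROC AUC over the five gesture classes.

    ``probs`` is an (n, 6) matrix of class probabilities.  Classes without
    both positives and negatives in the truth are flagged NaN and excluded
    from the macro average; an all-NaN result (single-class truth) is NaN.
    """
    truth = _as_labels(truth)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[0] != truth.shape[0]:
        raise ValueError("probs and truth must have equal length")
    per_class = {}
    for c in GESTURE_LABELS:
        pos = truth == c
        if pos.any() and (~pos).any():
            per_class[c] = float(roc_auc_score(pos, probs[:, c]))
        else:
            per_class[c] = float("nan")
    vals = [v for v in per_class.values() if np.isfinite(v)]
    value = float(np.mean(vals)) if vals else float("nan")
    return (value, per_class) if return_per_class else value


def macro_f1(pred, truth, average: str = "macro",
             return_per_class: bool = False):
    """Macro (or support-weighted) F1 over gesture classes present in the truth."""
    pred, truth = _as_labels(pred), _as_labels(truth)
    per_class = {}
    support = {}
    for c in GESTURE_LABELS:
        if not np.any(truth == c):
            continue
        tp = np.sum((truth == c) & (pred == c))
        fp = np.sum((truth != c) & (pred == c))
        fn = np.sum((truth == c) & (pred != c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        sens = tp / (tp + fn) if tp + fn else 0.0
        per_class[c] = (2 * prec * sens / (prec + sens)) if prec + sens else 0.0
        support[c] = int(np.sum(truth == c))
    if not per_class:
        value = float("nan")
    elif average == "weighted":
        w = np.asarray([support[c] for c in per_class], dtype=np.float64)
        value = float(np.average(list(per_class.values()), weights=w))
    else:
        value = float(np.mean(list(per_class.values())))
    return (value, per_class) if return_per_class else value


def iou(a, b) -> float:
    """Temporal IoU: overlapping positive bins over the union of positive bins.

    Both-empty arrays are the degenerate case this metric cannot express;
    defined here as 1.0 (see :func:`total_agreement` for the principled fix).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("arrays must have equal length")
    union = np.sum(a | b)
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


@dataclass
class AgreementScore:
    value: float
    n_bins: int
    positive_matches: int
    zero_matches: int
    positive_union: int


def total_agreement(a, b) -> AgreementScore:
    """IoU extended with matched-zero bins in intersection and union.

    Equals the bin-wise agreement rate (TP + TN) / N, and returns exactly
    1.0 when a class occurs in neither array.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("arrays must have equal length")
    if a.size < 1:
        raise ValueError("arrays must be non-empty")
    pos = int(np.sum(a & b))
    zero = int(np.sum(~a & ~b))
    union = int(np.sum(a | b))
    return AgreementScore(value=float((pos + zero) / (union + zero)),
                          n_bins=a.size, positive_matches=pos,
                          zero_matches=zero, positive_union=union)


def to_retained_blocks(P: np.ndarray, truth, block: int = 10
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate frame-level outputs into retained-prediction blocks.

    Sequence-level metrics are computed at the granularity of the retained
    blocks of sliding-window inference (``block`` frames each; a shorter
    final block holds the remainder).  Returns block probability means
    (renormalized), block predicted labels (argmax of the mean), and block
    truth labels (majority frame label, ties toward the lower label).
    """
    truth = _as_labels(truth)
    P = np.asarray(P, dtype=np.float64)
    if P.shape[0] != truth.shape[0]:
        raise ValueError("P and truth must have equal length")
    edges = np.arange(0, len(truth), block)
    probs, preds, truths = [], [], []
    for s in edges:
        sl = slice(s, min(s + block, len(truth)))
        p = P[sl].mean(axis=0)
        probs.append(p / p.sum())
        preds.append(int(np.argmax(p)))
        counts = np.bincount(truth[sl], minlength=P.shape[1])
        truths.append(int(np.argmax(counts)))
    return np.asarray(probs), np.asarray(preds), np.asarray(truths)


def stratified_agreement(results: Sequence[tuple[SegmentationResult, AnnotationTrack]],
                         strata: tuple[str, ...] = ("procedure", "class"),
                         fps: float = 25.0) -> pd.DataFrame:
    """Mean Total Agreement (with 95% CI half-width) per stratum.

    One score per (video, gesture class) compares predicted occupancy with
    the annotation's occupancy on the same normalized timeline.  Strata may
    combine ``procedure`` and ``class``; empty strata are omitted.
    """
    if not results:
        raise ValueError("no (segmentation, annotation) pairs supplied")
    rows = []
    for seg, track in results:
        truth_occ = annotation_occupancy(track, L=seg.L, fps=fps)
        for c in GESTURE_LABELS:
            pred_occ = seg.occupancy.get(c, np.zeros(seg.L, dtype=np.int8))
            ta = total_agreement(pred_occ, truth_occ[c])
            rows.append({"video_id": track.video_id, "procedure": track.procedure,
                         "class": f"G{c}", "total_agreement": ta.value})
    df = pd.DataFrame(rows)
    keys = [k for k in ("procedure", "class") if k in strata]
    out = []
    for name, g in df.groupby(keys, sort=True):
        m, (lo, hi) = _mean_ci(g["total_agreement"].tolist())
        rec = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        rec.update({"mean": m, "ci_half_width": (hi - lo) / 2.0,
                    "n_videos": g["video_id"].nunique(),
                    "degenerate_ci": len(g) < 2})
        out.append(rec)
    return pd.DataFrame(out)
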