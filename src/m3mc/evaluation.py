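"""Segmentation and classification metrics, per-slice profiles, and curves.

Volumetric overlap metrics are computed at the volume level from voxel
counts; empty-set corner cases are resolved explicitly (and logged) since
per-slice profiles routinely hit slices where one mask is empty:

* precision/recall/DSC/IoU with an empty denominator (0/0) are defined as 0
  unless both masks are empty, in which case the slice is omitted from
  profiles;
* RVD with empty ground truth and Hausdorff with an empty set are reported
  as NaN ("flagged missing").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "SegMetrics",
    "ClsMetrics",
    "seg_metrics",
    "hausdorff",
    "slice_profile",
    "pr_curve_ap",
    "roc_auc",
    "cls_metrics",
]


@dataclass
class SegMetrics:
    label: int
    iou: float
    dsc: float
    precision: float
    recall: float
    voe: float
    rvd: float

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "iou": self.iou,
            "dsc": self.dsc,
            "precision": self.precision,
            "recall": self.recall,
            "voe": self.voe,
            "rvd": self.rvd,
        }


@dataclass
class ClsMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


def _ratio(num: float, den: float, context: str) -> float:
    if den == 0:
        logger.debug("0/0 in %s defined as 0", context)
        return 0.0
    return num / den


def _overlap_counts(pred: np.ndarray, gt: np.ndarray):
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return tp, fp, fn


def seg_metrics(pred, gt, label: int) -> SegMetrics:
    """Volume-level overlap metrics for one structure label.

    ``pred``/``gt`` are :class:`~m3mc.volume_io.MultiClassMask` or raw label
    grids of equal shape. DSC = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN),
    VOE = 1 − |∩|/|∪|, RVD = |V_gt − V_pred| / V_gt.
    """
    p = _labels(pred)
    g = _labels(gt)
    if p.shape != g.shape:
        raise ValueError("pred and gt must be co-registered (same shape)")
    pb, gb = p == label, g == label
    tp, fp, fn = _overlap_counts(pb, gb)
    v_pred, v_gt = tp + fp, tp + fn
    union = tp + fp + fn
    rvd = abs(v_gt - v_pred) / v_gt if v_gt else float("nan")
    if v_gt == 0:
        logger.warning("empty ground truth for label %d: RVD flagged missing", label)
    return SegMetrics(
        label=label,
        iou=_ratio(tp, union, "IoU"),
        dsc=_ratio(2 * tp, 2 * tp + fp + fn, "DSC"),
        precision=_ratio(tp, tp + fp, "precision"),
        recall=_ratio(tp, tp + fn, "recall"),
        voe=1.0 - _ratio(tp, union, "VOE") if union else 0.0,
        rvd=rvd,
    )


def _labels(mask):
    return np.asarray(getattr(mask, "labels", mask))


def hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance (mm) between two binary voxel sets.

    max of the two directed distances over voxel centers; NaN if either set
    is empty.
    """
    pa = np.argwhere(np.asarray(a, dtype=bool))
    pb = np.argwhere(np.asarray(b, dtype=bool))
    if len(pa) == 0 or len(pb) == 0:
        logger.warning("Hausdorff of an empty set flagged missing")
        return float("nan")
    scale = np.asarray(spacing, dtype=np.float64)[: pa.shape[1]]
    pa = pa * scale
    pb = pb * scale
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def slice_profile(pred, gt, label: int, spacing=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Per-axial-slice 2-D DSC and Hausdorff, inferior → superior.

    Slices where both masks are empty for ``label`` are omitted; slices
    where exactly one is empty record DSC 0 and missing (NaN) Hausdorff.
    """
    p = _labels(pred)
    g = _labels(gt)
    if p.shape != g.shape:
        raise ValueError("pred and gt must be co-registered (same shape)")
    rows = []
    for z in range(p.shape[2]):
        pb, gb = p[:, :, z] == label, g[:, :, z] == label
        if not pb.any() and not gb.any():
            continue
        tp, fp, fn = _overlap_counts(pb, gb)
        dsc = _ratio(2 * tp, 2 * tp + fp + fn, "slice DSC")
        hd = hausdorff(pb, gb, spacing[:2]) if (pb.any() and gb.any()) else float("nan")
        rows.append({"z": z, "dsc": dsc, "hausdorff": hd, "tp": tp, "fp": fp, "fn": fn})
    return pd.DataFrame(rows, columns=["z", "dsc", "hausdorff", "tp", "fp", "fn"])


def pr_curve_ap(ious, thresholds=None):
    """Precision–recall curve over per-case IoU thresholds, and its AP.

    Each evaluated case contributes one predicted structure and one ground
    truth; at threshold ``t`` the case is a true positive iff its IoU ≥ t,
    otherwise it is simultaneously a false positive (spurious prediction)
    and a false negative (missed structure). Precision and recall therefore
    coincide at each threshold with the fraction of cases passing it. AP is
    the mean precision across the distinct achieved recall values.
    """
    ious = np.asarray(list(ious), dtype=np.float64)
    if ious.size == 0:
        raise ValueError("pr_curve_ap requires at least one evaluated case")
    if thresholds is None:
        thresholds = np.arange(0.05, 0.951, 0.05)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    frac = np.array([(ious >= t).mean() for t in thresholds])
    curve = pd.DataFrame({"threshold": thresholds, "precision": frac, "recall": frac})
    achieved = {}
    for r, p in zip(frac, frac):
        achieved[round(float(r), 12)] = max(p, achieved.get(round(float(r), 12), 0.0))
    ap = float(np.mean(list(achieved.values()))) if achieved else 0.0
    return curve, ap


def roc_auc(scores, labels, positive=1):
    """ROC curve by sweeping the class-probability threshold, AUC by the
    trapezoidal rule. Equals the pairwise concordance statistic
    P(score_pos > score_neg) + 0.5 P(tie) (asserted in tests)."""
    scores = np.asarray(list(scores), dtype=np.float64)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    if len(set(y.tolist())) < 2:
        logger.warning("single-class labels: AUC flagged missing")
        return pd.DataFrame(columns=["threshold", "fpr", "tpr"]), float("nan")
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr}), auc


def cls_metrics(scores, labels, positive=1, threshold: float = 0.5) -> ClsMetrics:
    """Accuracy / sensitivity / specificity at ``threshold`` plus AUC.

    ``scores`` are probabilities of the positive class; ``labels`` the true
    classes.
    """
    scores = np.asarray(list(scores), dtype=np.float64)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    _, auc = roc_auc(scores, labels, positive=positive)
    return ClsMetrics(
        accuracy=_ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        auc=auc,
    )
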