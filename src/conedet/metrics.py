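"""Detection evaluation: confusion counts, precision/recall, average
precision (all-point interpolation), F1 and the Matthews correlation
coefficient.

Positives are annotated target regions; negatives are background.  For
Mcc a count of true negatives is required, which detection benchmarks do
not define; here N_TN = (total number of anchor positions over all
three scales) - N_TP - N_FP - N_FN, i.e. background slots the detector
correctly left empty.  At a 416 input there are 10647 such positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .head import iou


@dataclass
class ConfusionCounts:
    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0
    n_tn: int = 0

    def __post_init__(self):
        if min(self.n_tp, self.n_fp, self.n_fn, self.n_tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    precision: float | None
    recall: float | None
    ap: float
    f1: float | None
    mcc: float | None
    counts: ConfusionCounts
    it_ms: float | None = None

    @property
    def fps(self) -> float | None:
        return 1000.0 / self.it_ms if self.it_ms else None

    def as_row(self) -> dict:
        return {"P": self.precision, "R": self.recall, "AP": self.ap,
                "F1": self.f1, "Mcc": self.mcc, "IT_ms": self.it_ms,
                "FPS": self.fps}


def total_prior_positions(input_side: int) -> int:
    """3 anchors per cell summed over the three grids (10647 at 416)."""
    return sum(3 * (input_side // s) ** 2 for s in (8, 16, 32))


def match_detections(dets, gts, iou_threshold: float = 0.5,
                     total_priors: int | None = None):
    """Greedy score-descending matching of detections to ground truth.

    A detection is a TP when its IoU with a still-unmatched ground-truth
    box reaches `iou_threshold` (it claims the best such box), otherwise
    an FP; leftover ground truths are FNs.  Returns (ConfusionCounts,
    per-detection TP/FP labels in score order).
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched = [False] * len(gts)
    labels: list[bool] = []
    tp = fp = 0
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if matched[j]:
                continue
            v = iou(dets[i].box, g[:4])
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp += 1
            labels.append(True)
        else:
            fp += 1
            labels.append(False)
    fn = matched.count(False)
    tn = 0
    if total_priors is not None:
        tn = max(0, total_priors - tp - fp - fn)
    return ConfusionCounts(tp, fp, fn, tn), labels


def precision_recall(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """(P, R); a zero denominator yields None (undefined, not 0)."""
    p = c.n_tp / (c.n_tp + c.n_fp) if (c.n_tp + c.n_fp) > 0 else None
    r = c.n_tp / (c.n_tp + c.n_fn) if (c.n_tp + c.n_fn) > 0 else None
    return p, r


def average_precision(labels: list[bool], n_gt: int) -> float:
    """Area under the P-R curve by all-point interpolation.

    `labels` are per-detection TP/FP flags already ranked by descending
    score; `n_gt` is the number of ground-truth boxes.
    """
    if n_gt < 1:
        raise ValueError("average precision needs at least one ground truth")
    if not labels:
        return 0.0
    tps = 0
    precisions, recalls = [], []
    for i, is_tp in enumerate(labels, start=1):
        tps += int(is_tp)
        precisions.append(tps / i)
        recalls.append(tps / n_gt)
    # precision envelope: max precision at recall >= r
    ap = 0.0
    prev_r = 0.0
    for i, r in enumerate(recalls):
        if r > prev_r:
            p_max = max(precisions[i:])
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient; None when a marginal is zero."""
    tp, fp, fn, tn = c.n_tp, c.n_fp, c.n_fn, c.n_tn
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom)
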