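"""Decoding raw head outputs into image-space detections and
duplicate suppression with DIoU-NMS.

DIoU-NMS replaces plain IoU overlap in greedy NMS with
IoU - centre-distance penalty, so overlapping boxes whose centres are
far apart (distinct nearby objects) survive suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .head import AnchorSet, HeadOutput, iou


@dataclass(frozen=True)
class Detection:
    """One detected object: box in input pixels (0-based, half-open),
    score = objectness x class probability, and the class id."""

    box: tuple[float, float, float, float]
    score: float
    class_id: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit
    return expit(x)


def decode(head: HeadOutput, anchors: AnchorSet, conf_threshold: float = 0.5,
           image_index: int = 0) -> list[Detection]:
    """Decode one image's head outputs into thresholded detections.

    Per cell/anchor: centre = (sigmoid(t_xy) + cell) * stride, size =
    anchor * exp(t_wh); score = sigmoid(objectness) * max class
    probability.  Boxes are clipped to the image.
    """
    if not (0.0 <= conf_threshold <= 1.0):
        raise ValueError("conf_threshold must lie in [0, 1]")
    side = head.input_side
    nc = head.num_classes
    out: list[Detection] = []
    for s_idx, raw in enumerate(head.maps):
        arr = raw.data if hasattr(raw, "data") else np.asarray(raw)
        n, _, s, _ = arr.shape
        stride = side // s
        r = arr[image_index].reshape(3, 5 + nc, s, s)
        a = anchors.for_scale(s_idx)
        gx = np.arange(s)[None, None, :]
        gy = np.arange(s)[None, :, None]
        cx = (_sigmoid(r[:, 0]) + gx) * stride
        cy = (_sigmoid(r[:, 1]) + gy) * stride
        w = a[:, 0][:, None, None] * np.exp(np.clip(r[:, 2], -12, 12))
        h = a[:, 1][:, None, None] * np.exp(np.clip(r[:, 3], -12, 12))
        obj = _sigmoid(r[:, 4])
        cls = _sigmoid(r[:, 5:5 + nc])
        cls_id = cls.argmax(axis=1)
        cls_p = cls.max(axis=1)
        score = obj * cls_p
        keep = np.argwhere(score >= conf_threshold)
        for (ai, yi, xi) in keep:
            x1 = float(np.clip(cx[ai, yi, xi] - w[ai, yi, xi] / 2, 0, side))
            y1 = float(np.clip(cy[ai, yi, xi] - h[ai, yi, xi] / 2, 0, side))
            x2 = float(np.clip(cx[ai, yi, xi] + w[ai, yi, xi] / 2, 0, side))
            y2 = float(np.clip(cy[ai, yi, xi] + h[ai, yi, xi] / 2, 0, side))
            if x2 <= x1 or y2 <= y1:
                continue
            out.append(Detection((x1, y1, x2, y2),
                                 float(score[ai, yi, xi]),
                                 int(cls_id[ai, yi, xi])))
    out.sort(key=lambda d: -d.score)
    return out


def diou(box_a, box_b) -> float:
    """Distance-IoU: IoU minus the squared centre distance normalised by
    the squared enclosing-box diagonal.  Range (-1, 1]."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    i = iou(box_a, box_b)
    acx, acy = (ax1 + ax2) / 2.0, (ay1 + ay2) / 2.0
    bcx, bcy = (bx1 + bx2) / 2.0, (by1 + by2) / 2.0
    rho2 = (acx - bcx) ** 2 + (acy - bcy) ** 2
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    c2 = cw * cw + ch * ch
    return i - (rho2 / c2 if c2 > 0 else 0.0)


def diou_nms(dets: list[Detection], nms_threshold: float = 0.45) -> list[Detection]:
    """Greedy class-wise non-maximum suppression under the DIoU overlap
    criterion; output sorted by descending score."""
    if not (0.0 < nms_threshold < 1.0):
        raise ValueError("nms_threshold must lie in (0, 1)")
    remaining = sorted(dets, key=lambda d: -d.score)
    kept: list[Detection] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [d for d in remaining
                     if d.class_id != best.class_id
                     or diou(d.box, best.box) <= nms_threshold]
    return kept


def iou_nms(dets: list[Detection], nms_threshold: float = 0.45) -> list[Detection]:
    """Plain IoU greedy NMS (reference for contrasting with DIoU-NMS)."""
    remaining = sorted(dets, key=lambda d: -d.score)
    kept: list[Detection] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [d for d in remaining
                     if d.class_id != best.class_id
                     or iou(d.box, best.box) <= nms_threshold]
    return kept
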