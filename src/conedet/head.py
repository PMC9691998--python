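"""YOLO prediction heads, anchor/target assignment and the composite
training loss (CIoU box regression + binary-cross-entropy confidence
and class terms).

Boxes are (xmin, ymin, xmax, ymax) in input-image pixels, 0-based and
half-open.  Raw head outputs are decoded with sigmoid centre offsets
inside the responsible grid cell and exponential width/height scaling
on the matched anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .backbone import FeaturePyramid

STRIDES = (8, 16, 32)


# -- box geometry (scalar / numpy) -------------------------------------

def iou(box_a, box_b) -> float:
    """Intersection-over-union; degenerate (zero-area) boxes give 0."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    area_a = max(0.0, ax2 - ax1) * max(0.0, ay2 - ay1)
    area_b = max(0.0, bx2 - bx1) * max(0.0, by2 - by1)
    if area_a <= 0.0 or area_b <= 0.0:
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def ciou_loss(pred, gt) -> float:
    """Complete-IoU loss: 1 - IoU + centre-distance penalty + aspect term."""
    gx1, gy1, gx2, gy2 = gt
    if gx2 - gx1 <= 0 or gy2 - gy1 <= 0:
        raise ValueError("ground-truth box has non-positive size")
    px1, py1, px2, py2 = pred
    i = iou(pred, gt)
    pcx, pcy = (px1 + px2) / 2.0, (py1 + py2) / 2.0
    gcx, gcy = (gx1 + gx2) / 2.0, (gy1 + gy2) / 2.0
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)
    c2 = cw * cw + ch * ch
    pw, ph = max(px2 - px1, 1e-9), max(py2 - py1, 1e-9)
    gw, gh = gx2 - gx1, gy2 - gy1
    v = (4.0 / math.pi ** 2) * (math.atan(gw / gh) - math.atan(pw / ph)) ** 2
    alpha = v / ((1.0 - i) + v) if v > 0 else 0.0
    return (1.0 - i) + (rho2 / c2 if c2 > 0 else 0.0) + alpha * v


def shape_iou(wh_a, wh_b) -> float:
    """IoU of two boxes centred at the origin (pure width/height match)."""
    inter = min(wh_a[0], wh_b[0]) * min(wh_a[1], wh_b[1])
    union = wh_a[0] * wh_a[1] + wh_b[0] * wh_b[1] - inter
    return inter / union if union > 0 else 0.0


# -- anchors -----------------------------------------------------------

@dataclass
class AnchorSet:
    """Nine (w, h) priors in input-image pixels, three per pyramid
    level: the smallest three belong to P3, the largest three to P5."""

    anchors: np.ndarray  # (9, 2), sorted by area ascending

    def __post_init__(self):
        arr = np.asarray(self.anchors, dtype=np.float64)
        if arr.shape != (9, 2):
            raise ValueError("an anchor set holds exactly nine (w, h) pairs")
        if (arr <= 0).any():
            raise ValueError("anchor sides must be positive")
        order = np.argsort(arr[:, 0] * arr[:, 1], kind="stable")
        self.anchors = arr[order]

    def for_scale(self, scale_index: int) -> np.ndarray:
        """Three anchors for pyramid level `scale_index` in {0,1,2}."""
        return self.anchors[3 * scale_index: 3 * scale_index + 3]

    def save(self, path):
        with open(path, "w") as fh:
            for w, h in self.anchors:
                fh.write(f"{w:.2f},{h:.2f}\n")

    @classmethod
    def load(cls, path) -> "AnchorSet":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    w, h = line.split(",")
                    pairs.append((float(w), float(h)))
        return cls(np.array(pairs))


# stock YOLOv4 priors at a 416 input, a reasonable generic default
DEFAULT_ANCHORS = AnchorSet(np.array([
    [12, 16], [19, 36], [40, 28],
    [36, 75], [76, 55], [72, 146],
    [142, 110], [192, 243], [459, 401],
], dtype=np.float64))


def scaled_default_anchors(input_side: int) -> AnchorSet:
    return AnchorSet(DEFAULT_ANCHORS.anchors * (input_side / 416.0))


# -- target assignment -------------------------------------------------

@dataclass
class TargetTensor:
    """Per-scale assignment masks and regression targets for one image.

    For each scale s: obj_mask/noobj_mask are (3, S, S) and disjoint;
    boxes is (3, S, S, 4) holding (cx, cy, w, h) in input pixels; cls is
    (3, S, S, num_classes).
    """

    grid_sides: tuple[int, int, int]
    num_classes: int
    obj_mask: list = field(default_factory=list)
    noobj_mask: list = field(default_factory=list)
    boxes: list = field(default_factory=list)
    cls: list = field(default_factory=list)
    lambda_noobj: float = 0.5


def assign_targets(gt_boxes, anchors: AnchorSet, grid_sides,
                   input_side: int, num_classes: int = 1,
                   ignore_threshold: float = 0.5,
                   lambda_noobj: float = 0.5) -> TargetTensor:
    """Assign each ground-truth box to one (scale, anchor, cell) slot.

    Matching is by highest shape-IoU over all nine priors.  When a later
    box claims an occupied slot it keeps it, and the earlier occupant is
    re-assigned to its best free alternative.  Priors whose shape-IoU
    with some ground truth exceeds `ignore_threshold` are excluded from
    the no-object mask at that box's cell.

    `gt_boxes` is a list of (xmin, ymin, xmax, ymax[, class_id]).
    """
    tt = TargetTensor(tuple(grid_sides), num_classes, lambda_noobj=lambda_noobj)
    for s in grid_sides:
        tt.obj_mask.append(np.zeros((3, s, s), dtype=bool))
        tt.noobj_mask.append(np.ones((3, s, s), dtype=bool))
        tt.boxes.append(np.zeros((3, s, s, 4), dtype=np.float32))
        tt.cls.append(np.zeros((3, s, s, num_classes), dtype=np.float32))

    # ranked anchor preferences per gt
    entries = []
    for g in gt_boxes:
        x1, y1, x2, y2 = g[:4]
        cls_id = int(g[4]) if len(g) > 4 else 0
        w, h = x2 - x1, y2 - y1
        if w <= 0 or h <= 0:
            raise ValueError("ground-truth boxes must have positive size")
        sious = np.array([shape_iou((w, h), tuple(a)) for a in anchors.anchors])
        order = np.argsort(-sious, kind="stable")
        entries.append({"box": (x1, y1, x2, y2), "cls": cls_id,
                        "order": order, "sious": sious})

    occupied: dict[tuple[int, int, int, int], int] = {}  # slot -> entry index
    assignment: dict[int, tuple[int, int, int, int]] = {}

    def cell_of(entry, scale):
        stride = input_side // tt.grid_sides[scale]
        x1, y1, x2, y2 = entry["box"]
        cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        gx = min(int(cx // stride), tt.grid_sides[scale] - 1)
        gy = min(int(cy // stride), tt.grid_sides[scale] - 1)
        return gx, gy

    def place(idx, allow_evict):
        e = entries[idx]
        for aidx in e["order"]:
            scale, a = divmod(int(aidx), 3)
            gx, gy = cell_of(e, scale)
            slot = (scale, a, gy, gx)
            holder = occupied.get(slot)
            if holder is None:
                occupied[slot] = idx
                assignment[idx] = slot
                return True
            if allow_evict and holder != idx:
                occupied[slot] = idx
                assignment[idx] = slot
                del assignment[holder]
                place(holder, allow_evict=False)
                return True
        return False

    for idx in range(len(entries)):
        place(idx, allow_evict=True)

    for idx, slot in assignment.items():
        scale, a, gy, gx = slot
        e = entries[idx]
        x1, y1, x2, y2 = e["box"]
        tt.obj_mask[scale][a, gy, gx] = True
        tt.noobj_mask[scale][a, gy, gx] = False
        tt.boxes[scale][a, gy, gx] = ((x1 + x2) / 2.0, (y1 + y2) / 2.0,
                                      x2 - x1, y2 - y1)
        tt.cls[scale][a, gy, gx, e["cls"]] = 1.0

    # ignore region: high shape-IoU priors at each gt's cell
    for e in entries:
        for aidx in range(9):
            if e["sious"][aidx] > ignore_threshold:
                scale, a = divmod(aidx, 3)
                gx, gy = cell_of(e, scale)
                tt.noobj_mask[scale][a, gy, gx] = False

    return tt


def stack_targets(targets: list[TargetTensor]) -> TargetTensor:
    """Stack per-image targets into batched (N, 3, S, S, ...) arrays."""
    first = targets[0]
    out = TargetTensor(first.grid_sides, first.num_classes,
                       lambda_noobj=first.lambda_noobj)
    for s in range(3):
        out.obj_mask.append(np.stack([t.obj_mask[s] for t in targets]))
        out.noobj_mask.append(np.stack([t.noobj_mask[s] for t in targets]))
        out.boxes.append(np.stack([t.boxes[s] for t in targets]))
        out.cls.append(np.stack([t.cls[s] for t in targets]))
    return out


# -- heads -------------------------------------------------------------

@dataclass
class HeadOutput:
    """Raw (pre-sigmoid) head outputs per scale.

    maps[s] has shape (N, 3*(5+num_classes), S_s, S_s) with the channel
    layout [tx, ty, tw, th, obj, cls...] per anchor.
    """

    maps: list  # three Tensors, P3/P4/P5 order
    input_side: int
    num_classes: int

    @property
    def grid_sides(self) -> tuple[int, int, int]:
        return tuple(m.shape[2] for m in self.maps)


class YoloHeads(nn.Module):
    """A 3x3 conv then a 1x1 projection to 3*(5+num_classes) channels,
    at each pyramid level."""

    def __init__(self, in_channels: tuple[int, int, int], num_classes: int = 1,
                 act: str = "leaky"):
        super().__init__()
        self.num_classes = num_classes
        nout = 3 * (5 + num_classes)
        self.stems = [nn.ConvBnAct(c, 2 * c, 3, act=act) for c in in_channels]
        self.preds = [nn.Conv2d(2 * c, nout, 1, bias=True) for c in in_channels]

    def forward(self, pyr: FeaturePyramid, input_side: int) -> HeadOutput:
        maps = [pred(stem(m.values))
                for stem, pred, m in zip(self.stems, self.preds, pyr.maps())]
        return HeadOutput(maps, input_side, self.num_classes)


# -- loss --------------------------------------------------------------

@dataclass
class LossBreakdown:
    ciou: float
    conf: float
    cls: float
    total: float
    total_tensor: Tensor | None = None


def _bce_logits(x: Tensor, target) -> Tensor:
    """Numerically stable elementwise BCE with logits."""
    absx = ag.relu(x) + ag.relu(-x)
    return ag.relu(x) - x * target + ag.log(1.0 + ag.exp(-absx))


def _ciou_terms(px1, py1, px2, py2, gbox: np.ndarray) -> Tensor:
    """Dense CIoU loss between decoded predictions and target boxes.

    Predicted corners are Tensors of shape (N, 3, S, S); `gbox` holds
    (cx, cy, w, h) targets of shape (N, 3, S, S, 4).
    """
    gcx, gcy = gbox[..., 0], gbox[..., 1]
    gw = np.maximum(gbox[..., 2], 1e-6)
    gh = np.maximum(gbox[..., 3], 1e-6)
    gx1, gy1 = gcx - gw / 2, gcy - gh / 2
    gx2, gy2 = gcx + gw / 2, gcy + gh / 2

    iw = ag.relu(ag.minimum(px2, gx2) - ag.maximum(px1, gx1))
    ih = ag.relu(ag.minimum(py2, gy2) - ag.maximum(py1, gy1))
    inter = iw * ih
    area_p = ag.relu(px2 - px1) * ag.relu(py2 - py1)
    union = area_p + gw * gh - inter
    iou_t = inter / (union + 1e-9)

    pcx, pcy = (px1 + px2) * 0.5, (py1 + py2) * 0.5
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    cw = ag.maximum(px2, gx2) - ag.minimum(px1, gx1)
    ch = ag.maximum(py2, gy2) - ag.minimum(py1, gy1)
    c2 = cw * cw + ch * ch + 1e-9

    pw = ag.relu(px2 - px1) + 1e-9
    ph = ag.relu(py2 - py1) + 1e-9
    v = (4.0 / math.pi ** 2) * (ag.atan(Tensor(gw / gh)) - ag.atan(pw / ph)) ** 2
    v_const = v.detach()
    iou_const = iou_t.detach()
    alpha = v_const.data / ((1.0 - iou_const.data) + v_const.data + 1e-9)
    return 1.0 - iou_t + rho2 / c2 + v * alpha


def decode_raw(raw: Tensor, anchors_scale: np.ndarray, stride: int,
               num_classes: int):
    """Split one raw head map into decoded box corners and logits.

    Returns (px1, py1, px2, py2, obj_logit, cls_logit) where corners are
    in input pixels with shape (N, 3, S, S) and cls_logit is
    (N, 3, num_classes, S, S).
    """
    n, _, s, _ = raw.shape
    r = raw.reshape(n, 3, 5 + num_classes, s, s)
    tx, ty = r[:, :, 0], r[:, :, 1]
    tw, th = r[:, :, 2], r[:, :, 3]
    obj = r[:, :, 4]
    cls = r[:, :, 5:5 + num_classes]
    gx = np.arange(s, dtype=np.float32)[None, None, None, :]
    gy = np.arange(s, dtype=np.float32)[None, None, :, None]
    cx = (ag.sigmoid(tx) + gx) * float(stride)
    cy = (ag.sigmoid(ty) + gy) * float(stride)
    aw = anchors_scale[:, 0].astype(np.float32)[None, :, None, None]
    ah = anchors_scale[:, 1].astype(np.float32)[None, :, None, None]
    pw = ag.exp(ag.clamp(tw, -12.0, 12.0)) * aw
    ph = ag.exp(ag.clamp(th, -12.0, 12.0)) * ah
    return (cx - pw * 0.5, cy - ph * 0.5, cx + pw * 0.5, cy + ph * 0.5,
            obj, cls)


def total_loss(pred: HeadOutput, tgt: TargetTensor, anchors: AnchorSet,
               lambda_noobj: float | None = None,
               keep_graph: bool = True) -> LossBreakdown:
    """The three-part detection loss, summed over positions and divided
    by the batch size.

    box term: CIoU at object positions; confidence term: BCE towards 1
    at object positions plus lambda_noobj-weighted BCE towards 0 at
    no-object positions; class term: BCE at object positions.
    """
    lam = tgt.lambda_noobj if lambda_noobj is None else lambda_noobj
    batch = pred.maps[0].shape[0]
    l_ciou = Tensor(0.0)
    l_conf = Tensor(0.0)
    l_cls = Tensor(0.0)
    for s_idx, raw in enumerate(pred.maps):
        if not np.isfinite(raw.data).all():
            bad = np.argwhere(~np.isfinite(raw.data))[0]
            raise FloatingPointError(
                f"non-finite head output at scale {s_idx}, index {tuple(bad)}")
        stride = pred.input_side // pred.grid_sides[s_idx]
        px1, py1, px2, py2, obj, cls = decode_raw(
            raw, anchors.for_scale(s_idx), stride, pred.num_classes)
        obj_m = tgt.obj_mask[s_idx].astype(np.float32)
        noobj_m = tgt.noobj_mask[s_idx].astype(np.float32)
        if obj_m.any():
            ciou_map = _ciou_terms(px1, py1, px2, py2, tgt.boxes[s_idx])
            l_ciou = l_ciou + (ciou_map * obj_m).sum()
            # class BCE at object positions
            tcls = np.moveaxis(tgt.cls[s_idx], -1, 2)  # (N,3,nc,S,S)
            cls_bce = _bce_logits(cls, tcls)
            l_cls = l_cls + (cls_bce * obj_m[:, :, None]).sum()
        conf_bce_obj = _bce_logits(obj, 1.0) * obj_m
        conf_bce_noobj = _bce_logits(obj, 0.0) * noobj_m
        l_conf = l_conf + conf_bce_obj.sum() + lam * conf_bce_noobj.sum()
    inv_b = 1.0 / float(batch)
    l_ciou, l_conf, l_cls = l_ciou * inv_b, l_conf * inv_b, l_cls * inv_b
    total = l_ciou + l_conf + l_cls
    return LossBreakdown(float(l_ciou.data), float(l_conf.data),
                         float(l_cls.data), float(total.data),
                         total_tensor=total if keep_graph else None)
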