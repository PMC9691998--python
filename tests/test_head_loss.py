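"""Box geometry, anchor assignment and the composite loss, checked
against hand computations and independent scalar-loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conedet.autograd import Tensor
from conedet.head import (AnchorSet, HeadOutput, TargetTensor, assign_targets,
                          ciou_loss, decode_raw, iou, shape_iou,
                          stack_targets, total_loss)

ANCHORS = AnchorSet(np.array([
    [4, 4], [8, 8], [12, 12],
    [20, 20], [28, 28], [40, 40],
    [60, 60], [90, 90], [140, 140],
], dtype=np.float64))


# -- IoU / CIoU --------------------------------------------------------

def test_iou_examples():
    assert iou((0, 0, 1, 1), (0, 0, 1, 1)) == 1.0
    assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0
    assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)
    assert iou((0, 0, 0, 1), (0, 0, 1, 1)) == 0.0  # degenerate box


def test_ciou_identical_boxes_is_zero():
    assert ciou_loss((3, 4, 10, 12), (3, 4, 10, 12)) == pytest.approx(0.0)


def test_ciou_hand_example_diagonal_touch():
    # unit boxes touching at a corner: IoU 0, centres sqrt(2) apart,
    # enclosure diagonal^2 = 8, equal aspect ratio so v = 0
    assert ciou_loss((0, 0, 1, 1), (1, 1, 2, 2)) == pytest.approx(1.25)


def test_ciou_aspect_only_mismatch_matches_scalar_oracle():
    # concentric, equal-area boxes differing only in aspect ratio
    pred = (-2.0, -0.5, 2.0, 0.5)   # 4 x 1
    gt = (-1.0, -1.0, 1.0, 1.0)     # 2 x 2
    i = iou(pred, gt)
    v = (4 / math.pi ** 2) * (math.atan(1.0) - math.atan(4.0)) ** 2
    alpha = v / ((1 - i) + v)
    expected = (1 - i) + 0.0 + alpha * v    # rho = 0
    assert ciou_loss(pred, gt) == pytest.approx(expected)


def test_ciou_rejects_degenerate_gt():
    with pytest.raises(ValueError):
        ciou_loss((0, 0, 1, 1), (0, 0, 0, 1))


@given(st.tuples(*[st.floats(0, 50) for _ in range(2)]),
       st.tuples(*[st.floats(1, 40) for _ in range(2)]),
       st.tuples(*[st.floats(0, 50) for _ in range(2)]),
       st.tuples(*[st.floats(1, 40) for _ in range(2)]))
@settings(max_examples=100, deadline=None)
def test_ciou_bounded(p0, pwh, g0, gwh):
    pred = (p0[0], p0[1], p0[0] + pwh[0], p0[1] + pwh[1])
    gt = (g0[0], g0[1], g0[0] + gwh[0], g0[1] + gwh[1])
    val = ciou_loss(pred, gt)
    assert 0.0 <= val <= 3.0   # 1-IoU <= 1, rho^2/c^2 < 1, alpha*v <= 1


# -- assignment --------------------------------------------------------

def test_small_box_lands_on_p3():
    # a box matching the smallest anchor must go to the stride-8 grid
    gt = [(50, 50, 54, 54)]
    tt = assign_targets(gt, ANCHORS, (16, 8, 4), 128)
    assert tt.obj_mask[0].sum() == 1
    assert tt.obj_mask[1].sum() == 0 and tt.obj_mask[2].sum() == 0
    a, gy, gx = np.argwhere(tt.obj_mask[0])[0]
    assert (gx, gy) == (6, 6)  # centre 52 / stride 8


def test_no_boxes_gives_all_noobj():
    tt = assign_targets([], ANCHORS, (16, 8, 4), 128)
    for s in range(3):
        assert not tt.obj_mask[s].any()
        assert tt.noobj_mask[s].all()


def test_masks_disjoint_and_every_gt_assigned():
    rng = np.random.default_rng(0)
    gts = []
    for _ in range(6):
        w, h = rng.uniform(4, 60, 2)
        x1 = rng.uniform(0, 128 - w)
        y1 = rng.uniform(0, 128 - h)
        gts.append((x1, y1, x1 + w, y1 + h))
    tt = assign_targets(gts, ANCHORS, (16, 8, 4), 128)
    assert sum(m.sum() for m in tt.obj_mask) == len(gts)
    for s in range(3):
        assert not (tt.obj_mask[s] & tt.noobj_mask[s]).any()


def test_same_slot_conflict_falls_back_to_next_anchor():
    # two identical boxes in the same cell competing for one anchor:
    # the later box keeps the best slot, the earlier one is re-assigned
    gt = [(48, 48, 56, 56), (49, 49, 57, 57)]  # both ~8x8, centre cell (6,6)
    tt = assign_targets(gt, ANCHORS, (16, 8, 4), 128)
    assert sum(m.sum() for m in tt.obj_mask) == 2
    # best anchor for an 8x8 box is index 1 (the 8x8 prior), on P3
    assert tt.obj_mask[0][1, 6, 6]
    np.testing.assert_allclose(tt.boxes[0][1, 6, 6],
                               (53.0, 53.0, 8.0, 8.0))  # the *second* box
    # the first box fell back to another free slot
    slots = np.argwhere(np.concatenate([m.ravel() for m in tt.obj_mask]))
    assert len(slots) == 2


def test_center_on_cell_boundary_uses_floor():
    gt = [(60, 60, 68, 68)]  # centre exactly 64 -> cell 8 at stride 8
    tt = assign_targets(gt, ANCHORS, (16, 8, 4), 128)
    a, gy, gx = np.argwhere(tt.obj_mask[0])[0]
    assert (gx, gy) == (8, 8)


def test_ignore_region_excluded_from_noobj():
    gt = [(48, 48, 56, 56)]  # 8x8: shape-IoU 1.0 with the 8x8 prior
    tt = assign_targets(gt, ANCHORS, (16, 8, 4), 128, ignore_threshold=0.5)
    # the 12x12 prior has shape-IoU (8*8)/(12*12) = 0.44 < 0.5 -> stays noobj
    assert tt.noobj_mask[0][2, 6, 6]
    assert not tt.noobj_mask[0][1, 6, 6]  # the assigned slot


# -- loss --------------------------------------------------------------

def _raw_heads(input_side, value=0.0, num_classes=1, seed=None):
    maps = []
    for s in (input_side // 8, input_side // 16, input_side // 32):
        shape = (1, 3 * (5 + num_classes), s, s)
        if seed is None:
            arr = np.full(shape, value, dtype=np.float32)
        else:
            arr = np.random.default_rng(seed + s).normal(
                0, 1, shape).astype(np.float32)
        maps.append(Tensor(arr))
    return HeadOutput(maps, input_side, num_classes)


def test_noobj_only_loss_closed_form():
    # no objects, all logits zero: every position contributes ln 2 of
    # confidence BCE weighted by lambda_noobj
    side = 64
    head = _raw_heads(side, 0.0)
    tt = stack_targets([assign_targets([], ANCHORS, head.grid_sides, side)])
    loss = total_loss(head, tt, ANCHORS)
    n_positions = sum(3 * s * s for s in head.grid_sides)
    assert loss.ciou == 0.0 and loss.cls == 0.0
    assert loss.conf == pytest.approx(0.5 * n_positions * math.log(2), rel=1e-5)
    assert loss.total == pytest.approx(loss.conf, rel=1e-6)


def test_perfect_prediction_loss_vanishes():
    side = 64
    # gt exactly the 8x8 anchor at the centre of P3 cell (3, 3)
    cx = (3 + 0.5) * 8
    gt = [(cx - 4, cx - 4, cx + 4, cx + 4)]
    tt = stack_targets([assign_targets(gt, ANCHORS, (8, 4, 2), side)])
    maps = []
    for s_idx, s in enumerate((8, 4, 2)):
        arr = np.zeros((1, 18, s, s), dtype=np.float32)
        arr.reshape(1, 3, 6, s, s)[:, :, 4] = -30.0   # background conf -> 0
        maps.append(arr)
    a, gy, gx = np.argwhere(tt.obj_mask[0][0])[0]
    maps[0].reshape(1, 3, 6, 8, 8)[0, a, 4, gy, gx] = 30.0  # conf -> 1
    maps[0].reshape(1, 3, 6, 8, 8)[0, a, 5, gy, gx] = 30.0  # class -> 1
    head = HeadOutput([Tensor(m) for m in maps], side, 1)
    loss = total_loss(head, tt, ANCHORS)
    assert loss.total < 1e-3


def test_loss_matches_independent_scalar_loop():
    """Random fixed-seed prediction/target pair vs a from-scratch
    scalar-loop evaluation of the three loss terms."""
    side = 32
    head = _raw_heads(side, seed=9)
    gts = [(4.0, 6.0, 16.0, 20.0), (18.0, 2.0, 30.0, 12.0)]
    per_image = assign_targets(gts, ANCHORS, head.grid_sides, side)
    tt = stack_targets([per_image])
    got = total_loss(head, tt, ANCHORS)

    def sig(x):
        return 1.0 / (1.0 + math.exp(-x))

    def bce(x, t):
        p = sig(x)
        return -(t * math.log(p) + (1 - t) * math.log(1 - p))

    l_ciou = l_conf = l_cls = 0.0
    for s_idx, s in enumerate(head.grid_sides):
        stride = side // s
        raw = head.maps[s_idx].data.reshape(3, 6, s, s)
        anch = ANCHORS.for_scale(s_idx)
        for a in range(3):
            for gy in range(s):
                for gx in range(s):
                    tx, ty, tw, th, to, tc = raw[a, :, gy, gx]
                    if per_image.obj_mask[s_idx][a, gy, gx]:
                        cx = (sig(tx) + gx) * stride
                        cy = (sig(ty) + gy) * stride
                        w = anch[a, 0] * math.exp(tw)
                        h = anch[a, 1] * math.exp(th)
                        bcx, bcy, bw, bh = per_image.boxes[s_idx][a, gy, gx]
                        l_ciou += ciou_loss(
                            (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                            (bcx - bw / 2, bcy - bh / 2,
                             bcx + bw / 2, bcy + bh / 2))
                        l_conf += bce(to, 1.0)
                        l_cls += bce(tc, per_image.cls[s_idx][a, gy, gx, 0])
                    elif per_image.noobj_mask[s_idx][a, gy, gx]:
                        l_conf += 0.5 * bce(to, 0.0)
    assert got.ciou == pytest.approx(l_ciou, rel=1e-3)
    assert got.conf == pytest.approx(l_conf, rel=1e-3)
    assert got.cls == pytest.approx(l_cls, rel=1e-3)
    assert got.total == pytest.approx(got.ciou + got.conf + got.cls, rel=1e-6)


def test_non_finite_prediction_reported_with_location():
    side = 32
    head = _raw_heads(side, 0.0)
    head.maps[1].data[0, 2, 1, 1] = np.nan
    tt = stack_targets([assign_targets([], ANCHORS, head.grid_sides, side)])
    with pytest.raises(FloatingPointError, match="scale 1"):
        total_loss(head, tt, ANCHORS)


# -- anchor set --------------------------------------------------------

def test_anchor_set_sorted_and_grouped(tmp_path):
    scrambled = np.array([[140, 140], [4, 4], [28, 28], [60, 60], [8, 8],
                          [90, 90], [12, 12], [40, 40], [20, 20]], dtype=float)
    aset = AnchorSet(scrambled)
    assert (aset.for_scale(0) == [[4, 4], [8, 8], [12, 12]]).all()
    assert (aset.for_scale(2) == [[60, 60], [90, 90], [140, 140]]).all()
    path = tmp_path / "anchors.txt"
    aset.save(path)
    loaded = AnchorSet.load(path)
    np.testing.assert_allclose(loaded.anchors, aset.anchors)


def test_anchor_set_validation():
    with pytest.raises(ValueError):
        AnchorSet(np.ones((8, 2)))
    bad = np.ones((9, 2))
    bad[3, 0] = -1
    with pytest.raises(ValueError):
        AnchorSet(bad)
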