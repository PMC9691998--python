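"""Anchor priors by k-means clustering of box shapes under the
1 - IoU(shape) distance, the standard recipe for YOLO-family anchors."""

from __future__ import annotations

import warnings

import numpy as np

from .head import AnchorSet


def _shape_iou_matrix(wh: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Pairwise shape IoU of boxes (n, 2) against centroids (k, 2)."""
    inter = (np.minimum(wh[:, None, 0], centroids[None, :, 0])
             * np.minimum(wh[:, None, 1], centroids[None, :, 1]))
    union = (wh[:, 0] * wh[:, 1])[:, None] + \
        (centroids[:, 0] * centroids[:, 1])[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def kmeans_anchors(boxes, k: int = 9, seed: int = 0,
                   max_iter: int = 300) -> AnchorSet:
    """Cluster (w, h) pairs into `k` anchor priors.

    Lloyd iterations with distance 1 - IoU(shape); centroids update as
    the member-wise mean.  Centroids are returned sorted by area and
    grouped three per pyramid scale by `AnchorSet`.
    """
    wh = np.asarray([(b[0], b[1]) for b in boxes], dtype=np.float64)
    if len(wh) < k:
        raise ValueError(f"need at least {k} boxes, got {len(wh)}")
    if (wh <= 0).any():
        raise ValueError("box sides must be positive")
    rng = np.random.default_rng(seed)
    uniq = np.unique(wh, axis=0)
    if len(uniq) == 1:
        warnings.warn("all boxes identical; returning k copies of that shape")
        return AnchorSet(np.repeat(uniq, k, axis=0))
    if len(uniq) == k:
        return AnchorSet(uniq)
    centroids = wh[rng.choice(len(wh), size=k, replace=False)]
    assign = np.full(len(wh), -1)
    for _ in range(max_iter):
        dist = 1.0 - _shape_iou_matrix(wh, centroids)
        new_assign = dist.argmin(axis=1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit box
                centroids[j] = wh[dist.min(axis=1).argmax()]
    return AnchorSet(centroids)
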