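"""Freeze-thaw training and test-set evaluation.

Training follows the two-phase schedule: the backbone is frozen for the
first `freeze_epochs` epochs at `lr_frozen`, then the whole network is
thawed and the learning rate resets to the (smaller) `lr_unfrozen`.
The learning rate additionally decays multiplicatively each epoch.
Optimisation is Adam; mosaic augmentation can mix training images.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import nn
from .data import ImageSample, mosaic
from .head import AnchorSet, assign_targets, stack_targets, total_loss
from .metrics import (MetricsReport, average_precision, f1_score,
                      match_detections, mcc, precision_recall,
                      total_prior_positions)
from .model import ConeDetector, ModelConfig, images_to_batch
from .postprocess import decode, diou_nms


@dataclass
class TrainConfig:
    total_epochs: int = 150
    freeze_epochs: int = 60
    lr_frozen: float = 1e-3
    lr_unfrozen: float = 5e-5
    batch_size: int = 8
    lr_decay: float = 0.95          # per-epoch multiplicative decay
    seed: int = 0
    input_side: int = 416
    mosaic: bool = True
    mosaic_prob: float = 0.5
    lambda_noobj: float = 0.5
    ignore_threshold: float = 0.5

    def __post_init__(self):
        if not (0 <= self.freeze_epochs < self.total_epochs):
            raise ValueError("freeze_epochs must be < total_epochs")
        if self.lr_frozen <= 0 or self.lr_unfrozen <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainResult:
    log: list = field(default_factory=list)   # per-epoch dict records
    best_loss: float = float("inf")
    best_path: Path | None = None
    last_path: Path | None = None


def _epoch_lr(tc: TrainConfig, epoch: int) -> float:
    if epoch < tc.freeze_epochs:
        return tc.lr_frozen * tc.lr_decay ** epoch
    return tc.lr_unfrozen * tc.lr_decay ** (epoch - tc.freeze_epochs)


def _make_batches(samples, tc: TrainConfig, rng) -> list[list[ImageSample]]:
    idx = rng.permutation(len(samples))
    out = []
    for i in range(0, len(idx), tc.batch_size):
        batch = [samples[j] for j in idx[i:i + tc.batch_size]]
        if tc.mosaic and len(samples) >= 4 and rng.random() < tc.mosaic_prob:
            picks = [samples[j] for j in rng.integers(0, len(samples), 4)]
            batch[rng.integers(0, len(batch))] = mosaic(
                picks, tc.input_side, seed=int(rng.integers(0, 2 ** 31 - 1)))
        out.append(batch)
    return out


def train_step(model: ConeDetector, batch: list[ImageSample],
               optimizer: nn.Adam, tc: TrainConfig):
    """One full forward/backward/update on a batch; returns the loss."""
    images = images_to_batch(batch)
    head = model(images)
    targets = stack_targets([
        assign_targets(s.boxes, model.anchors, head.grid_sides,
                       model.cfg.input_side, model.cfg.num_classes,
                       tc.ignore_threshold, tc.lambda_noobj)
        for s in batch])
    loss = total_loss(head, targets, model.anchors)
    if not np.isfinite(loss.total):
        raise FloatingPointError(f"non-finite loss: {loss}")
    optimizer.zero_grad()
    loss.total_tensor.backward()
    optimizer.step()
    return loss


def train(model: ConeDetector, samples: list[ImageSample], tc: TrainConfig,
          out_dir=None, log_every: int = 1, start_epoch: int = 0) -> TrainResult:
    """Run the freeze-thaw schedule over `samples`.

    Writes a line-delimited JSON log and best/last checkpoints when
    `out_dir` is given; aborts with the epoch/step on non-finite loss.
    `start_epoch` > 0 continues the epoch counter of a resumed run
    (optimizer moments start fresh).
    """
    if not samples:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(tc.seed + start_epoch)
    result = TrainResult()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    optimizer = nn.Adam(model.parameters(), lr=tc.lr_frozen)
    model.train()
    model.freeze_backbone(start_epoch < tc.freeze_epochs)
    mode = "a" if start_epoch else "w"
    log_fh = open(out / "train_log.jsonl", mode) if out is not None else None
    try:
        for epoch in range(start_epoch, tc.total_epochs):
            if epoch == tc.freeze_epochs:
                model.freeze_backbone(False)
            lr = _epoch_lr(tc, epoch)
            optimizer.lr = lr
            epoch_losses = []
            for step, batch in enumerate(_make_batches(samples, tc, rng)):
                try:
                    loss = train_step(model, batch, optimizer, tc)
                except FloatingPointError as exc:
                    raise FloatingPointError(
                        f"epoch {epoch} step {step}: {exc}") from exc
                epoch_losses.append(loss.total)
            record = {"epoch": epoch, "lr": lr,
                      "frozen": epoch < tc.freeze_epochs,
                      "loss": float(np.mean(epoch_losses))}
            result.log.append(record)
            if log_fh is not None and epoch % log_every == 0:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            if record["loss"] < result.best_loss:
                result.best_loss = record["loss"]
                if out is not None:
                    result.best_path = out / "best.npz"
                    model.save_checkpoint(result.best_path,
                                          extra={"epoch": epoch})
    finally:
        if log_fh is not None:
            log_fh.close()
    if out is not None:
        result.last_path = out / "last.npz"
        model.save_checkpoint(result.last_path,
                              extra={"epoch": tc.total_epochs - 1})
    return result


def recalibrate_batchnorm(model: ConeDetector, samples: list[ImageSample],
                          batch_size: int = 4):
    """Recompute batch-norm running statistics as the exact cumulative
    average over forward passes on `samples` (train-mode statistics).

    Standard finalisation for small-dataset training, where the
    momentum-smoothed running averages can sit far from the statistics
    of an outlier training image; evaluation then sees the same
    normalisation the optimiser trained against.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0
        bn._recal_count = 1
    model.train()
    with ag.no_grad():
        for i in range(0, len(samples), batch_size):
            model(images_to_batch(samples[i:i + batch_size]))
    for bn in bns:
        bn._recal_count = 0
    model.eval()


def overfit_experiment(seed: int = 0, n_images: int = 6, side: int = 256,
                       total_epochs: int = 150, freeze_epochs: int = 60,
                       lr_frozen: float = 1e-3, lr_unfrozen: float = 5e-4,
                       conf_threshold: float = 0.25,
                       batch_size: int | None = 3) -> dict:
    """Scaled-down learning check: overfit a fresh detector on a few
    seeded synthetic scenes and measure train-set recall at IoU 0.5.

    Runs the freeze-thaw schedule at a reduced 256-pixel input with
    anchors clustered from the scenes' own boxes.  At smaller sides the
    size regime degenerates (boxes of a few pixels cannot meet an IoU
    0.5 bar and near-identical anchors scatter targets onto the coarse
    grids), so 256 is the smallest faithful resolution.  Returns the
    initial and final loss, their ratio, and the train-set P/R/AP.
    """
    from .anchors import kmeans_anchors
    from .data import make_synthetic_dataset
    samples = make_synthetic_dataset(n_images, side=side, seed=seed)
    wh = [(x2 - x1, y2 - y1) for s in samples
          for x1, y1, x2, y2, _ in s.boxes]
    anchors = kmeans_anchors(wh, seed=seed)
    model = ConeDetector(ModelConfig(input_side=side, init_seed=seed), anchors)
    tc = TrainConfig(total_epochs=total_epochs, freeze_epochs=freeze_epochs,
                     lr_frozen=lr_frozen, lr_unfrozen=lr_unfrozen,
                     lr_decay=0.98, batch_size=batch_size or n_images,
                     input_side=side,
                     mosaic=False, seed=seed)
    result = train(model, samples, tc)
    losses = [r["loss"] for r in result.log]
    recalibrate_batchnorm(model, samples, batch_size=tc.batch_size)
    report = evaluate(model, samples, conf_threshold=conf_threshold,
                      iou_threshold=0.5, measure_time=False)
    return {"loss_initial": losses[0], "loss_final": losses[-1],
            "loss_ratio": losses[-1] / losses[0],
            "recall": report.recall, "precision": report.precision,
            "ap": report.ap, "n_images": n_images, "side": side}


def evaluate(model: ConeDetector, samples: list[ImageSample],
             conf_threshold: float = 0.5, nms_threshold: float = 0.45,
             iou_threshold: float = 0.5, measure_time: bool = True) -> MetricsReport:
    """Decode -> DIoU-NMS -> greedy matching over a test set; reports
    P, R, AP, F1, Mcc and the median per-image inference time."""
    if not samples:
        raise ValueError("test set is empty")
    model.eval()
    all_labeled = []     # (score, is_tp) across the set
    tp = fp = fn = 0
    n_gt_total = 0
    times = []
    priors_per_image = total_prior_positions(model.cfg.input_side)
    for s in samples:
        img = s.pixels.transpose(2, 0, 1).astype(np.float32)[None] / 255.0
        t0 = time.perf_counter()
        with ag.no_grad():
            head = model(img)
        dets = diou_nms(decode(head, model.anchors, conf_threshold),
                        nms_threshold)
        times.append((time.perf_counter() - t0) * 1000.0)
        counts, labels = match_detections(dets, s.boxes, iou_threshold)
        tp += counts.n_tp
        fp += counts.n_fp
        fn += counts.n_fn
        n_gt_total += len(s.boxes)
        for d, lab in zip(sorted(dets, key=lambda d: -d.score), labels):
            all_labeled.append((d.score, lab))
    from .metrics import ConfusionCounts
    tn = max(0, priors_per_image * len(samples) - tp - fp - fn)
    counts = ConfusionCounts(tp, fp, fn, tn)
    p, r = precision_recall(counts)
    all_labeled.sort(key=lambda t: -t[0])
    ap = average_precision([lab for _, lab in all_labeled], n_gt_total) \
        if n_gt_total else 0.0
    f1 = f1_score(p, r) if (p is not None and r is not None) else None
    return MetricsReport(p, r, ap, f1, mcc(counts), counts,
                         it_ms=float(np.median(times)) if measure_time else None)
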