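# Methods

## Problem and model

`conedet` detects small, roughly circular pine-cone targets in forest
photographs with a lightweight anchor-based one-stage detector.  The
network has three parts:

**Backbone.** EfficientNet-b0: a strided 3×3 stem followed by seven
MBConv stages (repeats 1,1,2,2,3,3,4,1; output widths
32,16,24,40,80,112,192,320).  Each MBConv expands with a 1×1
convolution (factor 6, skipped when the factor is 1), applies a
depthwise 3×3 or 5×5 convolution, a squeeze-and-excitation gate at
ratio 0.25 of the block's input width, and a 1×1 projection; an
identity skip is added when stride is 1 and the widths match.  The
taps at stages 4, 6 and 8 give the pyramid levels P3/P4/P5 at strides
8/16/32 with 40/112/320 channels.  Backbone activations are Swish
(x·σ(x)); a config switch substitutes H-Swish.

**Neck.** A 1×1 "channel transfer" first maps the pyramid to a reduced
budget; four designs are supported — (128,256,512), (256,256,256),
(128,128,128), (64,64,64) — with the third as default.  SPP (max pools
5/9/13 concatenated with the identity, then a 1×1 projection) enlarges
the receptive field on P5.  A single three-level BiFPN pass follows: a
top-down path creates an intermediate mid-level node, then a bottom-up
path re-fuses each level with cross-layer skips from the original
inputs.  Every fusion node combines its inputs by fast normalised
weighted addition, out = Σ relu(wᵢ)·xᵢ / (ε + Σ relu(wⱼ)) with
learnable scalars wᵢ and ε = 1e-4, so the coefficients are
non-negative and sum to slightly below one.  Each fused level passes
through a depthwise-separable 3×3 block, and an ECA attention block:
global average pooling per channel, a 1-D convolution of adaptive odd
length k(C) = nearest-odd((log₂C + 1)/2) (ties resolved to the smaller
odd number, so k(128)=3, k(256)=5), a sigmoid, and channelwise
rescaling.  Neck activations are leaky ReLU by default and H-Swish
(x·Relu6(x+3)/6) in the full configuration.  A YOLOv4-style PANet neck
(concatenation fusion, CBL3/CBL5 stacks, 128/256/512 outputs) is kept
as the ablation baseline; at the default design the BiFPN neck has
~0.49 M parameters against PANet's ~17.4 M.

**Heads and loss.** Each level carries a 3×3 conv-BN-activation stem
and a 1×1 projection to 3·(5+num_classes) channels (three anchors per
cell; tx,ty,tw,th, objectness, class logits).  Boxes decode as
centre = (σ(t_xy)+cell)·stride and size = anchor·exp(t_wh).  The loss
is L = L_ciou + L_conf + L_class: CIoU box regression at object
positions (1 − IoU + ρ²/c² + αv with v the arctan aspect term and
α = v/((1−IoU)+v), α treated as a constant in the gradient), binary
cross-entropy on objectness (target 1 at object slots, 0 at no-object
slots weighted by λ_noobj = 0.5), and BCE over classes at object
slots; all terms are summed and divided by the batch size.  Each
ground-truth box is assigned to the (scale, anchor) pair with the
highest shape-IoU, at the cell containing its centre (floor
convention); when a later box claims an occupied slot it keeps it and
the earlier box is re-assigned to its best free alternative.  Priors
with shape-IoU above 0.5 to some ground truth are excluded from the
no-object mask.  Inference uses DIoU-NMS: greedy suppression with
IoU − ρ²/c² as the overlap measure (threshold 0.45), which retains
overlapping boxes whose centres are far apart.

Anchors come from k-means over box shapes under the 1 − IoU(shape)
distance, sorted by area and grouped three per level.

## Numerical engine

The network runs on a compact reverse-mode autodiff core over numpy
float32 arrays.  Dense convolutions use im2col + BLAS matmul (1×1
kernels short-circuit to a channel matmul); depthwise convolutions use
strided window views with einsum; max pooling is same-padded with
tie-aware gradient scatter.  The tape is single-use: after backward,
graph edges are cleared so activation memory is reclaimed immediately.
Batch normalisation uses batch statistics in training mode and running
averages (momentum 0.1) in eval mode.  Weights are Kaiming-normal from
a dedicated initialisation stream so that a model build is fully
determined by its init seed.  Optimisation is Adam (β = 0.9/0.999).
Checkpoints are single `.npz` files keyed by parameter name with a
JSON manifest, so they survive module refactors.

## Training schedule

Defaults mirror the published regime: 150 epochs, the first 60 with
the backbone frozen at initial learning rate 1e-3, then a thaw with
the rate reset to 5e-5, batch size 8, input 416×416, Adam, and mosaic
augmentation at the batch level.  The published "random decay"
schedule is under-specified; we implement a per-epoch multiplicative
decay of ×0.95 with a config hook (cosine annealing is exposed nowhere
because the reference regime explicitly leaves it off).  The
freeze-thaw contract is tested bitwise: a frozen epoch leaves every
backbone parameter unchanged.

## Synthetic scenes

The generator emulates the acquisition regime of the target
application: two scene types — "ground" (brown/green correlated-noise
leaf litter) and "tree" (sky gradient, canopy patches, branch
strokes) — each holding 1–15 ellipsoidal cone-like targets with a
criss-cross scale-lattice texture.  Box areas are drawn log-normally
around a median area fraction of 0.57% of the image (the modal
300×300 target in a 5312×2988 frame) and clipped to 0.01%–1.4%
(mirroring the 25²–600² extremes); fractions, not absolute pixels,
carry the size regime, and the default generation side is 416.
Illumination varies by a uniform brightness factor in [0.7, 1.15].
Exact bounding boxes come from the drawn ellipse masks; every box is
at least half target pixels by construction.  The generator is fully
seed-deterministic.

What the synthetic scenes do **not** capture: real cone appearance
(occlusion by needles, specularities, motion blur), background clutter
statistics, perspective and camera effects.  Tests passing on these
scenes therefore demonstrate that the architecture, losses, training
schedule and evaluation pipeline are implemented correctly and can fit
data of the stated size regime — not that the published accuracies
transfer to real forest imagery.

Offline expansion appends, per image, one copy transformed by a
uniformly chosen member of {contrast about the per-image mean, channel
gains in [0.7, 1.3], Gaussian noise σ ∈ [5, 15], salt-and-pepper with
rate in [0.02, 0.08]} — all geometry-preserving, so a 768-scene set
becomes exactly 1536.  The 8:2 train/test split happens at the source
level: an augmented copy always follows its source, avoiding leakage.
Mosaic composes four images at a random split point in [0.3, 0.7] of
the canvas; boxes keep ≥ 25% of their area or are dropped.

## Evaluation

Greedy score-descending matching at IoU 0.5 produces TP/FP/FN; AP uses
all-point interpolation of the precision envelope.  The Matthews
correlation coefficient needs true negatives, which detection
benchmarks leave undefined; here N_TN = total anchor slots across the
three grids (10647 at input 416) minus TP+FP+FN — i.e. background
slots correctly left empty.  This convention is a package choice and
is stated wherever Mcc is reported.  Inference time is reported as the
median per-image forward+postprocess wall time, and FPS as 1000/IT;
both are measurements, never asserted values.

## Scaled-down learning check

The end-to-end check (`conedet.train.overfit_experiment`, also run by
`scripts/acceptance.py`) trains a freshly initialised detector on six
seeded synthetic scenes at a 256×256 input with anchors clustered from
those scenes' own boxes, running the 150-epoch freeze-thaw schedule (60
frozen epochs at rate 1e-3, then a thaw at 5e-4 — a working rate for a
randomly initialised backbone at this miniature scale, where the
published 5e-5 is a fine-tune rate — with decay ×0.98 and batch 3),
then evaluating on the same scenes at confidence 0.25 and IoU 0.5.
256 pixels is the smallest faithful resolution for this check: below
it the size regime degenerates — the smallest targets shrink to a few
pixels, where an IoU-0.5 bar demands sub-pixel regression, and the
clustered anchors become near-identical so targets scatter onto the
coarse stride-32 grid and collide in its few cells.  After training,
batch-norm running statistics are recalibrated over the training
scenes (`recalibrate_batchnorm`): with six images, momentum-smoothed
averages can sit far from an outlier scene's statistics and collapse
its detections in eval mode.

The run takes about fifteen minutes on one CPU; it reduces the loss
to roughly a twentieth of its initial value, and at the suite's fixed
seed recovers train-set recall above 0.8.  Because the
experiment is tiny (six scenes, tens of boxes), recall varies
substantially across generator seeds: seeds whose tree scenes place
many cones directly on similarly-coloured branch clutter can leave a
camouflage-hard image only partially memorised within the step
budget.  That difficulty is an intended property of the scene
generator (forest cones are brown-on-brown targets), so it is
documented rather than removed.  Precision stays modest in this
regime — a from-scratch run this short mostly learns objectness and
relies on anchor shapes for box geometry — which is expected and not
part of the check.

## Design choices on genuinely open points

- The adaptive ECA kernel formula is printed ambiguously in the
  reference material; we use nearest-odd((log₂C+1)/2) with ties to the
  smaller odd number, consistent with the cited attention design
  (γ=2, b=1) and with the stated preference for smaller padding.
- The CIoU α/v typography is likewise garbled at the source; the
  canonical formulation is implemented.
- Confidence BCE at object positions targets 1 (not the IoU value).
- SE blocks are included in MBConv (ratio 0.25) as in canonical
  EfficientNet-b0, although some renderings of the block omit them; a
  flag (`se_ratio`) exposes the alternative.
- Fusion uses relu-clamped fast normalised weights with ε = 1e-4, the
  standard form of the cited BiFPN; resampling is nearest-neighbour ×2
  upward and strided 3×3 convolution downward.
- ECA is applied once per level, after the bottom-up fusion pass.
- AP uses all-point interpolation (the integral definition), not the
  11-point variant.
- FPS is reported per second (the reference's own IT↔FPS arithmetic is
  1000/IT despite a "per minute" phrase).
- The stock-width baseline for ablation group 0 uses a plain strided
  conv trunk at CSPDarkNet53's output widths (256/512/1024), because
  the heavy CSP backbone is outside this package's scope; it exists so
  the ablation harness can construct and train all five groups, and
  its accuracy is meaningless.

## Known limitations

- CPU-only: practical training is limited to reduced resolutions and
  small datasets; the full 416×416 × 1536-image regime is out of desk
  reach and the published accuracy/FPS tables are not reproduced here.
- Single-class focus: multi-class paths exist (class loss, class-wise
  NMS) but are exercised mainly at num_classes = 1.
- No pretrained weights: backbones initialise randomly; a checkpoint
  hook exists but no model zoo.
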