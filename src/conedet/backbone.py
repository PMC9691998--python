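"""EfficientNet-b0 feature extractor.

Produces the three pyramid levels P3/P4/P5 (strides 8/16/32; 40/112/320
channels at the defaults) used by the detection neck.  The stage plan is
the standard b0 layout: a strided 3x3 stem followed by seven MBConv
stages with repeats 1,1,2,2,3,3,4,1 and output widths
32,16,24,40,80,112,192,320.

MBConv = mobile inverted bottleneck: 1x1 expansion, depthwise
convolution, squeeze-and-excitation, 1x1 projection, with an identity
skip when stride is 1 and the widths match.  The backbone activation is
Swish by default (switchable to H-Swish); batch normalisation follows
every convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

# (operator, expansion, kernel, stride, out_channels, repeat) per stage
DEFAULT_STAGE_SPECS: list[tuple[str, int, int, int, int, int]] = [
    ("stem_conv", 1, 3, 2, 32, 1),
    ("mbconv", 1, 3, 1, 16, 1),
    ("mbconv", 6, 3, 2, 24, 2),
    ("mbconv", 6, 5, 2, 40, 2),   # P3 tap
    ("mbconv", 6, 5, 2, 80, 3),
    ("mbconv", 6, 5, 1, 112, 3),  # P4 tap
    ("mbconv", 6, 5, 2, 192, 4),
    ("mbconv", 6, 3, 1, 320, 1),  # P5 tap
]

PYRAMID_STAGES = (3, 5, 7)  # zero-based indices of the P3/P4/P5 taps


@dataclass
class BackboneConfig:
    input_side: int = 416
    stage_specs: list = field(default_factory=lambda: [tuple(s) for s in DEFAULT_STAGE_SPECS])
    width_multiplier: float = 1.0
    depth_multiplier: float = 1.0
    se_ratio: float = 0.25
    activation: str = "swish"

    def __post_init__(self):
        if self.input_side % 32 != 0:
            raise ValueError(
                f"input side {self.input_side} is not divisible by 32; the "
                "backbone downsamples five times and needs a multiple of 32")
        if not (0.0 < self.se_ratio <= 1.0):
            raise ValueError("se_ratio must lie in (0, 1]")
        for spec in self.stage_specs:
            op, _, k, s, _, _ = spec
            if op not in ("stem_conv", "mbconv"):
                raise ValueError(f"unknown stage operator {op!r}")
            if k not in (3, 5):
                raise ValueError("kernel side must be 3 or 5")
            if s not in (1, 2):
                raise ValueError("stride must be 1 or 2")


@dataclass
class FeatureMap:
    """A batch of feature maps (N, C, H, W) at a fixed stride."""

    values: Tensor
    stride: int

    @property
    def channels(self) -> int:
        return self.values.shape[1]

    @property
    def side(self) -> int:
        return self.values.shape[2]


@dataclass
class FeaturePyramid:
    p3: FeatureMap
    p4: FeatureMap
    p5: FeatureMap

    def __post_init__(self):
        if (self.p3.stride, self.p4.stride, self.p5.stride) != (8, 16, 32):
            raise ValueError("pyramid strides must be (8, 16, 32)")

    @property
    def channels(self) -> tuple[int, int, int]:
        return (self.p3.channels, self.p4.channels, self.p5.channels)

    def maps(self) -> list[FeatureMap]:
        return [self.p3, self.p4, self.p5]


class SqueezeExcite(nn.Module):
    """Channel gating: GAP -> 1x1 reduce -> swish -> 1x1 expand -> sigmoid."""

    def __init__(self, channels: int, reduced: int):
        super().__init__()
        self.reduce = nn.Conv2d(channels, reduced, 1, bias=True)
        self.expand = nn.Conv2d(reduced, channels, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        g = x.mean(axis=(2, 3), keepdims=True)
        g = self.reduce(g)
        g = g * ag.sigmoid(g)
        g = ag.sigmoid(self.expand(g))
        return x * g


class MBConv(nn.Module):
    """Mobile inverted bottleneck convolution block."""

    def __init__(self, cin: int, cout: int, expansion: int, kernel: int,
                 stride: int, se_ratio: float = 0.25, activation: str = "swish"):
        super().__init__()
        if kernel not in (3, 5):
            raise ValueError("kernel side must be 3 or 5")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        mid = cin * expansion
        self.use_skip = stride == 1 and cin == cout
        self.act = nn.Activation(activation)
        self.expand = None
        if expansion != 1:
            self.expand = nn.Conv2d(cin, mid, 1, bias=False)
            self.expand_bn = nn.BatchNorm2d(mid)
        self.dw = nn.DepthwiseConv2d(mid, kernel, stride)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.se = None
        if se_ratio > 0:
            self.se = SqueezeExcite(mid, max(1, int(cin * se_ratio)))
        self.project = nn.Conv2d(mid, cout, 1, bias=False)
        self.project_bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.expand is not None:
            h = self.act(self.expand_bn(self.expand(h)))
        h = self.act(self.dw_bn(self.dw(h)))
        if self.se is not None:
            h = self.se(h)
        h = self.project_bn(self.project(h))
        if self.use_skip:
            if h.shape != x.shape:
                raise ValueError(
                    f"skip path shape mismatch: {x.shape} vs {h.shape}")
            h = h + x
        return h


def mbconv_block(x: FeatureMap, expansion: int, kernel: int, stride: int,
                 out_channels: int, se_ratio: float = 0.25,
                 activation: str = "swish", seed: int = 0) -> FeatureMap:
    """Build a freshly initialised MBConv block and apply it to `x`.

    Convenience wrapper used for shape-contract checks; real models hold
    `MBConv` modules directly.
    """
    nn.seed_init(seed)
    block = MBConv(x.channels, out_channels, expansion, kernel, stride,
                   se_ratio, activation)
    block.eval()
    with ag.no_grad():
        out = block(x.values)
    return FeatureMap(out, x.stride * stride)


class EfficientNetB0(nn.Module):
    """The full backbone; `forward` returns a FeaturePyramid."""

    def __init__(self, cfg: BackboneConfig | None = None):
        super().__init__()
        self.cfg = cfg or BackboneConfig()
        act = self.cfg.activation
        self.stages: list[nn.Module] = []
        cin = 3
        for op, expansion, k, stride, cout, repeat in self.cfg.stage_specs:
            blocks: list[nn.Module] = []
            if op == "stem_conv":
                blocks.append(nn.ConvBnAct(cin, cout, k, stride, act=act))
            else:
                for r in range(repeat):
                    # only the first repetition carries the stride
                    s = stride if r == 0 else 1
                    c0 = cin if r == 0 else cout
                    blocks.append(MBConv(c0, cout, expansion, k, s,
                                         self.cfg.se_ratio, act))
            self.stages.append(nn.Sequential(*blocks))
            cin = cout

    def forward_stages(self, x: Tensor) -> list[FeatureMap]:
        """Run all stages, returning every stage output with its stride."""
        side = x.shape[2]
        if x.shape[1] != 3:
            raise ValueError("backbone expects a 3-channel input")
        if side % 32 != 0 or x.shape[3] != side:
            raise ValueError(
                f"input side {side}x{x.shape[3]} must be square and "
                "divisible by 32")
        outs: list[FeatureMap] = []
        stride = 1
        for stage, spec in zip(self.stages, self.cfg.stage_specs):
            stride *= spec[3]
            x = stage(x)
            outs.append(FeatureMap(x, stride))
        return outs

    def forward(self, x: Tensor) -> FeaturePyramid:
        outs = self.forward_stages(x)
        p3, p4, p5 = (outs[i] for i in PYRAMID_STAGES)
        return FeaturePyramid(p3, p4, p5)


def backbone_forward(image: np.ndarray | Tensor, cfg: BackboneConfig | None = None,
                     seed: int = 0) -> FeaturePyramid:
    """One-shot forward pass through a freshly initialised backbone.

    `image` is (3, S, S) or (N, 3, S, S).
    """
    nn.seed_init(seed)
    net = EfficientNetB0(cfg)
    net.eval()
    arr = image.data if isinstance(image, Tensor) else np.asarray(image, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    with ag.no_grad():
        return net(Tensor(arr))


class CSPPlaceholderBackbone(nn.Module):
    """Stand-in for the heavy CSPDarkNet53 backbone of stock YOLOv4.

    Used only so the full-network ablation baseline (group 0) can be
    constructed and exercised: a plain strided conv trunk that produces
    pyramid levels at the original YOLOv4 widths (256/512/1024).  It is
    NOT CSPDarkNet53 and makes no claim to its accuracy; it reproduces
    only the interface and the parameter-scale regime.
    """

    WIDTHS = (256, 512, 1024)

    def __init__(self, activation: str = "leaky"):
        super().__init__()
        a = activation
        self.stem = nn.Sequential(nn.ConvBnAct(3, 32, 3, 2, act=a),
                                  nn.ConvBnAct(32, 64, 3, 2, act=a),
                                  nn.ConvBnAct(64, 128, 3, 2, act=a))
        self.s3 = nn.Sequential(nn.ConvBnAct(128, 256, 3, 1, act=a),
                                nn.ConvBnAct(256, 256, 3, 1, act=a))
        self.s4 = nn.Sequential(nn.ConvBnAct(256, 512, 3, 2, act=a),
                                nn.ConvBnAct(512, 512, 3, 1, act=a))
        self.s5 = nn.Sequential(nn.ConvBnAct(512, 1024, 3, 2, act=a),
                                nn.ConvBnAct(1024, 1024, 3, 1, act=a))

    def forward(self, x: Tensor) -> FeaturePyramid:
        h = self.stem(x)
        c3 = self.s3(h)
        c4 = self.s4(c3)
        c5 = self.s5(c4)
        return FeaturePyramid(FeatureMap(c3, 8), FeatureMap(c4, 16),
                              FeatureMap(c5, 32))
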