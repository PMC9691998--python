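"""Feature-fusion neck.

The lightweight neck first maps the backbone pyramid to a reduced
channel budget (four candidate designs; the 128/128/128 design is the
default), optionally applies SPP to the deepest level, then runs a
three-level BiFPN pass: a top-down path creating an intermediate
mid-level node, and a bottom-up path with cross-layer skips from the
original inputs.  Each fusion node combines its inputs by fast
normalised weighted addition (relu-clamped learnable scalars).  An
efficient-channel-attention (ECA) block reweights each fused output
level, and the neck activations can be switched to H-Swish.

A YOLOv4-style PANet neck (concatenation fusion, CBL3/CBL5 stacks) is
included as the ablation baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .backbone import FeatureMap, FeaturePyramid

CHANNEL_DESIGNS: dict[int, tuple[int, int, int]] = {
    1: (128, 256, 512),
    2: (256, 256, 256),
    3: (128, 128, 128),
    4: (64, 64, 64),
}


@dataclass(frozen=True)
class ChannelDesign:
    design_id: int = 3

    @property
    def channels(self) -> tuple[int, int, int]:
        if self.design_id not in CHANNEL_DESIGNS:
            raise ValueError(f"channel design must be 1..4, got {self.design_id}")
        return CHANNEL_DESIGNS[self.design_id]


# -- activations as plain functions (numpy in / numpy out) -------------

def hard_swish(x):
    """H-Swish: x * Relu6(x + 3) / 6 (piecewise-linear Swish surrogate)."""
    if isinstance(x, Tensor):
        return x * ag.clamp(x + 3.0, 0.0, 6.0) * (1.0 / 6.0)
    a = np.asarray(x, dtype=np.float64)
    out = a * np.clip(a + 3.0, 0.0, 6.0) / 6.0
    return out if out.ndim else float(out)


def swish(x, beta: float = 1.0):
    """Swish: x * sigmoid(beta * x)."""
    if isinstance(x, Tensor):
        return x * ag.sigmoid(x * beta)
    a = np.asarray(x, dtype=np.float64)
    out = a / (1.0 + np.exp(-beta * a))
    return out if out.ndim else float(out)


# -- ECA ---------------------------------------------------------------

def eca_kernel_size(channels: int) -> int:
    """Adaptive 1-D kernel size: nearest odd to (log2(C)+1)/2, ties to
    the smaller odd number, never below 1."""
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    t = (math.log2(channels) + 1.0) / 2.0
    if t <= 1.0:
        return 1
    m = math.floor(t)
    lo = m if m % 2 == 1 else m - 1
    hi = lo + 2
    return lo if (t - lo) <= (hi - t) else hi


@dataclass(frozen=True)
class EcaConfig:
    channels: int

    @property
    def kernel_size(self) -> int:
        return eca_kernel_size(self.channels)


class ECA(nn.Module):
    """Efficient channel attention: GAP -> short 1-D conv across the
    channel axis -> sigmoid -> channelwise rescale."""

    def __init__(self, channels: int):
        super().__init__()
        self.k = eca_kernel_size(channels)
        self.weight = nn.Parameter(np.full(self.k, 1.0 / self.k, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        g = x.mean(axis=(2, 3))                     # (N, C)
        scale = ag.sigmoid(ag.conv1d_channels(g, self.weight))
        return x * scale.reshape(n, c, 1, 1)


def eca_attention(x: Tensor | np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    """Functional ECA on an (N, C, H, W) or (C, H, W) feature map."""
    arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    mod = ECA(arr.shape[1])
    if weight is not None:
        if len(weight) != mod.k:
            raise ValueError(f"expected kernel of size {mod.k}")
        mod.weight.data = np.asarray(weight, dtype=np.float32)
    with ag.no_grad():
        out = mod(Tensor(arr))
    return Tensor(out.data[0]) if squeeze else out


# -- weighted fusion ---------------------------------------------------

def _one_hot(n: int, i: int) -> np.ndarray:
    v = np.zeros(n, dtype=np.float32)
    v[i] = 1.0
    return v


def weighted_fuse(inputs: list[Tensor | np.ndarray], weights, eps: float = 1e-4) -> Tensor:
    """Functional weighted fusion with explicit scalar weights."""
    xs = [x if isinstance(x, Tensor) else Tensor(x) for x in inputs]
    if len(xs) < 2:
        raise ValueError("fusion needs at least two inputs")
    w = np.maximum(np.asarray(weights, dtype=np.float32), 0.0)
    if len(w) != len(xs):
        raise ValueError("one weight per input required")
    denom = float(w.sum()) + eps
    acc = xs[0] * float(w[0] / denom)
    for x, wi in zip(xs[1:], w[1:]):
        acc = acc + x * float(wi / denom)
    return acc


# -- SPP ---------------------------------------------------------------

class SPP(nn.Module):
    """Spatial pyramid pooling on the deepest level: concatenate the
    identity with same-size max pools, then project back with a 1x1."""

    def __init__(self, channels: int, pool_sides: tuple[int, ...] = (5, 9, 13),
                 act: str = "leaky"):
        super().__init__()
        for k in pool_sides:
            if k % 2 == 0:
                raise ValueError("pool sides must be odd")
        self.pool_sides = tuple(pool_sides)
        self.project = nn.ConvBnAct(channels * (1 + len(pool_sides)), channels,
                                    1, act=act)

    def forward(self, x: Tensor) -> Tensor:
        feats = [x] + [ag.maxpool2d_same(x, k) for k in self.pool_sides]
        return self.project(ag.concat(feats, axis=1))


def spp(x: FeatureMap, pool_sides=(5, 9, 13), act: str = "leaky",
        seed: int = 0) -> FeatureMap:
    """One-shot SPP on a feature map (fresh weights; shape contract helper)."""
    nn.seed_init(seed)
    mod = SPP(x.channels, tuple(pool_sides), act)
    mod.eval()
    with ag.no_grad():
        return FeatureMap(mod(x.values), x.stride)


# -- BiFPN -------------------------------------------------------------

class SeparableConvBlock(nn.Module):
    """Depthwise 3x3 + pointwise 1x1 + BN + activation (per fusion node)."""

    def __init__(self, cin: int, cout: int, act: str):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(cin, 3)
        self.pw = nn.Conv2d(cin, cout, 1, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.Activation(act)

    def forward(self, x):
        return self.act(self.bn(self.pw(self.dw(x))))


class _Resample(nn.Module):
    """Aligns a level to a neighbour: nearest 2x upsample or strided
    3x3 conv downsample, with a 1x1 projection if channels differ."""

    def __init__(self, cin: int, cout: int, direction: str, act: str):
        super().__init__()
        self.direction = direction
        self.project = None
        self.down = None
        if direction == "down":
            self.down = nn.ConvBnAct(cin, cout, 3, 2, act=act)
        elif cin != cout:
            self.project = nn.ConvBnAct(cin, cout, 1, act=act)

    def forward(self, x):
        if self.direction == "down":
            return self.down(x)
        if self.project is not None:
            x = self.project(x)
        return ag.upsample_nearest2(x)


class BiFPN(nn.Module):
    """One three-level BiFPN pass with cross-layer skip connections.

    Nodes (c3/c4/c5 are the transferred inputs):
        m4   = fuse(c4, up(c5))              -- intermediate mid node
        out3 = fuse(c3, up(m4))
        out4 = fuse(c4, m4, down(out3))      -- cross-layer skip from c4
        out5 = fuse(c5, down(out4))          -- skip from the original c5
    """

    def __init__(self, channels: tuple[int, int, int], act: str = "leaky",
                 eps: float = 1e-4):
        super().__init__()
        c3, c4, c5 = channels
        self.up54 = _Resample(c5, c4, "up", act)
        self.up43 = _Resample(c4, c3, "up", act)
        self.down34 = _Resample(c3, c4, "down", act)
        self.down45 = _Resample(c4, c5, "down", act)
        self.fuse_m4 = WeightedFusionFast(2, eps)
        self.fuse_out3 = WeightedFusionFast(2, eps)
        self.fuse_out4 = WeightedFusionFast(3, eps)
        self.fuse_out5 = WeightedFusionFast(2, eps)
        self.conv_m4 = SeparableConvBlock(c4, c4, act)
        self.conv_out3 = SeparableConvBlock(c3, c3, act)
        self.conv_out4 = SeparableConvBlock(c4, c4, act)
        self.conv_out5 = SeparableConvBlock(c5, c5, act)

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        c3, c4, c5 = pyr.p3.values, pyr.p4.values, pyr.p5.values
        m4 = self.conv_m4(self.fuse_m4([c4, self.up54(c5)]))
        out3 = self.conv_out3(self.fuse_out3([c3, self.up43(m4)]))
        out4 = self.conv_out4(self.fuse_out4([c4, m4, self.down34(out3)]))
        out5 = self.conv_out5(self.fuse_out5([c5, self.down45(out4)]))
        return FeaturePyramid(FeatureMap(out3, 8), FeatureMap(out4, 16),
                              FeatureMap(out5, 32))


class WeightedFusionFast(nn.Module):
    """Module form of `weighted_fuse` with learnable scalar weights."""

    def __init__(self, n_inputs: int, eps: float = 1e-4):
        super().__init__()
        if n_inputs < 2:
            raise ValueError("fusion needs at least two inputs")
        self.eps = eps
        self.weights = nn.Parameter(np.ones(n_inputs, dtype=np.float32))

    def coefficients(self) -> np.ndarray:
        w = np.maximum(self.weights.data, 0.0)
        return w / (self.eps + w.sum())

    def forward(self, inputs: list[Tensor]) -> Tensor:
        n = self.weights.shape[0]
        if len(inputs) != n:
            raise ValueError("wrong number of fusion inputs")
        w = ag.relu(self.weights)
        denom = w.sum() + self.eps
        acc = None
        for i, x in enumerate(inputs):
            coeff = (w * _one_hot(n, i)).sum() / denom
            term = x * coeff
            acc = term if acc is None else acc + term
        return acc


class ChannelTransfer(nn.Module):
    """1x1 convolutions mapping the backbone pyramid onto the reduced
    channel budget of a `ChannelDesign`."""

    def __init__(self, in_channels: tuple[int, int, int],
                 design: ChannelDesign = ChannelDesign(3), act: str = "leaky"):
        super().__init__()
        self.design = design
        outs = design.channels
        self.convs = [nn.ConvBnAct(cin, cout, 1, act=act)
                      for cin, cout in zip(in_channels, outs)]

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        maps = [FeatureMap(conv(m.values), m.stride)
                for conv, m in zip(self.convs, pyr.maps())]
        return FeaturePyramid(*maps)


def channel_transfer(pyr: FeaturePyramid, design: ChannelDesign,
                     act: str = "leaky", seed: int = 0) -> FeaturePyramid:
    """One-shot channel transfer with fresh weights (contract helper)."""
    nn.seed_init(seed)
    mod = ChannelTransfer(pyr.channels, design, act)
    mod.eval()
    with ag.no_grad():
        return mod(pyr)


class BiFPNNeck(nn.Module):
    """Channel transfer -> optional SPP(p5) -> BiFPN -> optional ECA."""

    def __init__(self, in_channels: tuple[int, int, int],
                 design: ChannelDesign = ChannelDesign(3),
                 use_eca: bool = True, use_spp: bool = True,
                 hswish: bool = False, fusion_eps: float = 1e-4):
        super().__init__()
        act = "hswish" if hswish else "leaky"
        self.transfer = ChannelTransfer(in_channels, design, act)
        c3, c4, c5 = design.channels
        self.spp = SPP(c5, act=act) if use_spp else None
        self.bifpn = BiFPN((c3, c4, c5), act=act, eps=fusion_eps)
        self.eca = [ECA(c) for c in (c3, c4, c5)] if use_eca else None
        self.out_channels = design.channels

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        pyr = self.transfer(pyr)
        if self.spp is not None:
            pyr = FeaturePyramid(pyr.p3, pyr.p4,
                                 FeatureMap(self.spp(pyr.p5.values), 32))
        pyr = self.bifpn(pyr)
        if self.eca is not None:
            maps = [FeatureMap(eca(m.values), m.stride)
                    for eca, m in zip(self.eca, pyr.maps())]
            pyr = FeaturePyramid(*maps)
        return pyr


class PANetNeck(nn.Module):
    """YOLOv4-style PANet baseline: top-down then bottom-up aggregation
    with concatenation fusion and CBL3/CBL5 stacks; optional SPP on p5.
    Output widths are the stock YOLOv4 128/256/512.
    """

    OUT = (128, 256, 512)

    def __init__(self, in_channels: tuple[int, int, int], use_spp: bool = True,
                 act: str = "leaky"):
        super().__init__()
        b3, b4, b5 = in_channels
        o3, o4, o5 = self.OUT
        self.pre5 = _cbl_stack(b5, o5, 3, act)
        self.spp = SPP(o5, act=act) if use_spp else None
        self.post5 = _cbl_stack(o5, o5, 3, act)
        self.lat4 = nn.ConvBnAct(b4, o4, 1, act=act)
        self.red54 = nn.ConvBnAct(o5, o4, 1, act=act)
        self.td4 = _cbl_stack(o4 * 2, o4, 5, act)
        self.lat3 = nn.ConvBnAct(b3, o3, 1, act=act)
        self.red43 = nn.ConvBnAct(o4, o3, 1, act=act)
        self.td3 = _cbl_stack(o3 * 2, o3, 5, act)
        self.down34 = nn.ConvBnAct(o3, o4, 3, 2, act=act)
        self.bu4 = _cbl_stack(o4 * 2, o4, 5, act)
        self.down45 = nn.ConvBnAct(o4, o5, 3, 2, act=act)
        self.bu5 = _cbl_stack(o5 * 2, o5, 5, act)
        self.out_channels = self.OUT

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        c5 = self.pre5(pyr.p5.values)
        if self.spp is not None:
            c5 = self.spp(c5)
        c5 = self.post5(c5)
        c4 = self.td4(ag.concat([self.lat4(pyr.p4.values),
                                 ag.upsample_nearest2(self.red54(c5))], axis=1))
        c3 = self.td3(ag.concat([self.lat3(pyr.p3.values),
                                 ag.upsample_nearest2(self.red43(c4))], axis=1))
        d4 = self.bu4(ag.concat([self.down34(c3), c4], axis=1))
        d5 = self.bu5(ag.concat([self.down45(d4), c5], axis=1))
        return FeaturePyramid(FeatureMap(c3, 8), FeatureMap(d4, 16),
                              FeatureMap(d5, 32))


def _cbl_stack(cin: int, cout: int, depth: int, act: str) -> nn.Sequential:
    """CBL3/CBL5: alternating 1x1 / 3x3 conv-BN-activation layers."""
    layers: list[nn.Module] = []
    c = cin
    for i in range(depth):
        if i % 2 == 0:
            layers.append(nn.ConvBnAct(c, cout, 1, act=act))
            c = cout
        else:
            layers.append(nn.ConvBnAct(c, cout, 3, act=act))
    return nn.Sequential(*layers)


def panet_neck(pyr: FeaturePyramid, seed: int = 0) -> FeaturePyramid:
    """One-shot PANet pass with fresh weights (contract helper)."""
    nn.seed_init(seed)
    mod = PANetNeck(pyr.channels)
    mod.eval()
    with ag.no_grad():
        return mod(pyr)


def bifpn_pass(pyr: FeaturePyramid, seed: int = 0) -> FeaturePyramid:
    """One-shot BiFPN pass with fresh weights (contract helper)."""
    nn.seed_init(seed)
    mod = BiFPN(pyr.channels)
    mod.eval()
    with ag.no_grad():
        return mod(pyr)
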