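"""Layer library on top of the autograd core: modules, convolution
blocks, batch normalisation, activations and the Adam optimizer."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with named-parameter traversal and train/eval modes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}")
            elif name.startswith("running_") and isinstance(val, np.ndarray):
                yield full, val

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter in checkpoint: {name}")
                if params[name].shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{params[name].shape} vs {arr.shape}")
                params[name].data = arr.astype(np.float32)
            elif kind == "buffer":
                if name not in buffers:
                    raise KeyError(f"unknown buffer in checkpoint: {name}")
                buffers[name][...] = arr
            else:
                raise KeyError(f"malformed checkpoint key: {key}")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# -- initialisation ----------------------------------------------------

def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the weight-initialisation stream (call before building a model)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = (k - 1) // 2
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming(_INIT_RNG, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int, stride: int = 1, bias: bool = False):
        super().__init__()
        self.stride, self.padding = stride, (k - 1) // 2
        self.weight = Parameter(_kaiming(_INIT_RNG, (channels, k, k), k * k))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ag.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._recal_count = 0   # > 0 while recalibrating: cumulative average

    def forward(self, x: Tensor):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            if self._recal_count > 0:
                m = 1.0 / self._recal_count
                self._recal_count += 1
            else:
                m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mean) / ag.sqrt(var + self.eps)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


# -- activations -------------------------------------------------------

class Activation(Module):
    """Wraps one of the functional activations by name."""

    def __init__(self, kind: str):
        super().__init__()
        if kind not in ("swish", "hswish", "leaky", "relu", "linear"):
            raise ValueError(f"unknown activation: {kind}")
        self.kind = kind

    def forward(self, x):
        if self.kind == "swish":
            return x * ag.sigmoid(x)
        if self.kind == "hswish":
            return x * ag.clamp(x + 3.0, 0.0, 6.0) * (1.0 / 6.0)
        if self.kind == "leaky":
            return ag.maximum(x, 0.1 * x)
        if self.kind == "relu":
            return ag.relu(x)
        return x


class ConvBnAct(Module):
    """Conv -> BatchNorm -> activation, the basic block everywhere
    ("CBL" in the YOLOv4 lineage when the activation is leaky ReLU)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 act: str = "leaky"):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = Activation(act)

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


# -- optimizer ---------------------------------------------------------

class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
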