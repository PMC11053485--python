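"""Neural-network building blocks and optimisation on top of :mod:`.autodiff`.

Layers store their weights as ``Tensor`` objects with ``requires_grad=True``;
:class:`Module` provides recursive parameter collection, train/eval switching
and a flat name→array state dict used by the checkpoint format.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def _walk(name: str, value):
    """Yield (path, leaf) pairs recursing through Modules and nested lists."""
    if isinstance(value, (Module, Tensor, np.ndarray)):
        yield name, value
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk(f"{name}.{i}", item)


class Module:
    """Base class: recursive parameter discovery over attributes and
    (possibly nested) lists of sub-modules."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in self.__dict__.items():
            yield from _walk(name, value)

    def modules(self):
        for _, child in self._children():
            if isinstance(child, Module):
                yield child
                yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, child in self._children():
            if isinstance(child, Module):
                yield from child.named_parameters(f"{prefix}{name}.")
            elif isinstance(child, Tensor) and child.requires_grad:
                yield f"{prefix}{name}", child

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    # -- checkpoint support: includes non-trainable buffers (running stats)
    def named_buffers(self, prefix: str = ""):
        for name, child in self._children():
            if isinstance(child, Module):
                yield from child.named_buffers(f"{prefix}{name}.")
            elif isinstance(child, np.ndarray):
                yield f"{prefix}{name}", child

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(arr, dtype=params[name].data.dtype)
            else:
                obj = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
                setattr(obj, leaf, np.asarray(arr))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.weight = parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        if len(lead) > 1:
            x = x.reshape((-1, x.shape[-1]))
        out = x @ self.weight + self.bias
        if len(lead) > 1:
            out = out.reshape(lead + (out.shape[-1],))
        return out


class Conv1x1(Module):
    """Pointwise convolution on channel-first maps, realised as a matmul."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (c_in + c_out))
        self.weight = parameter(rng.uniform(-bound, bound, size=(c_in, c_out)))
        self.bias = parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h = x.reshape((B, C, H * W)).transpose((0, 2, 1)).reshape((B * H * W, C))
        h = h @ self.weight + self.bias
        return h.reshape((B, H * W, -1)).transpose((0, 2, 1)).reshape((B, -1, H, W))


class DepthwiseConv3x3(Module):
    """3×3 depthwise convolution (stride 1, zero padding 1) via shifted slices."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / 18.0)
        self.weight = parameter(rng.uniform(-bound, bound, size=(channels, 3, 3)))
        self.bias = parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return ad.dwconv3x3(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(channels))
        self.beta = parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        shape = (1, C, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(C).astype(np.float32)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(C).astype(np.float32)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xn = (x - mu) / ad.sqrt(var + self.eps)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    """Normalisation over the last axis with learnable affine."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ad.sqrt(var + self.eps) * self.gamma + self.beta


class DropPath(Module):
    """Stochastic depth: drop the whole residual branch per sample in training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate <= 1.0:
            raise ValueError("drop_path rate must be in [0, 1]")
        self.rate = float(rate)
        self.rng = np.random.default_rng(0)  # reseeded by the model at build time

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if self.rate == 1.0:
            return x * 0.0
        B = x.shape[0]
        keep = (self.rng.random(B) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        mask = keep.reshape((B,) + (1,) * (x.ndim - 1))
        return x * Tensor(mask)


class Adam:
    """Adam; optional global-norm gradient clipping (off by default, so the
    relative weighting of loss terms is exactly what the objective states)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total_steps: int, lr_max: float, lr_min: float) -> float:
    """Cosine annealing from ``lr_max`` down to ``lr_min`` over ``total_steps``."""
    if total_steps <= 1:
        return lr_max
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * frac))
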