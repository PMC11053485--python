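"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with the closure needed to
back-propagate through the operation that produced it.  The op set is exactly
what the biomass models and losses in this package need: broadcasting
arithmetic, 2-D matmul, reshapes/transposes, basic slicing, zero padding,
reductions, the usual pointwise nonlinearities, and nearest-neighbour
upsampling.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which seeds the output with ones and walks the graph
in reverse topological order.

Graph construction is skipped entirely when no input requires a gradient or
inside a :func:`no_grad` block, so evaluation passes carry no autodiff cost.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray):
        # op closures never mutate emitted gradients in place, so storing the
        # reference on first accumulation is safe (re-binding, never +=)
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        # iterative topological sort
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __pow__(self, c):
        return pow_const(self, c)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    # --------------------------------------------------------------- wrappers
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    @property
    def T(self):
        return transpose(self, None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# -------------------------------------------------------------------- ops
# python scalars stay python scalars so float32 graphs are not upcast
def add(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        a = _as_tensor(a)
        data = a.data + b

        def backward(g):
            a._accumulate(g)

        return _make(data, (a,), backward)
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        a = _as_tensor(a)
        data = a.data * b

        def backward(g):
            a._accumulate(g * b)

        return _make(data, (a,), backward)
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        return mul(a, 1.0 / b)
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(data, (a, b), backward)


def pow_const(a, c) -> Tensor:
    a = _as_tensor(a)
    c = float(c)
    data = a.data**c

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c * a.data ** (c - 1.0))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def getitem(a, key) -> Tensor:
    """Basic slicing only (slices / ints / ellipsis); no fancy indexing."""
    a = _as_tensor(a)
    data = a.data[key]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[key] = g  # basic slices never alias, so assignment suffices
            a._accumulate(full)

    return _make(data, (a,), backward)


def pad2d(a, pad: int) -> Tensor:
    """Zero-pad the last two axes by ``pad`` on each side."""
    a = _as_tensor(a)
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    data = np.pad(a.data, width)
    sl = (Ellipsis, slice(pad, pad + a.data.shape[-2]), slice(pad, pad + a.data.shape[-1]))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[sl])

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return tsum(a, axis, keepdims) * (1.0 / n)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (0.5 / data))

    return _make(data, (a,), backward)


def tabs(a) -> Tensor:
    a = _as_tensor(a)
    data = np.abs(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.sign(a.data))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    return _make(data, (a,), backward)


def gelu(a) -> Tensor:
    """GELU, sigmoid approximation x·σ(1.702x)."""
    a = _as_tensor(a)
    x = a.data
    s = 1.0 / (1.0 + np.exp(-1.702 * x))
    data = x * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (s * (1.0 + 1.702 * x * (1.0 - s))))

    return _make(data, (a,), backward)


def clip_min(a, floor: float) -> Tensor:
    """Elementwise ``max(a, floor)`` with subgradient 0 on the floor."""
    a = _as_tensor(a)
    mask = a.data > floor
    data = np.where(mask, a.data, floor)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(data, (a,), backward)


def upsample_nearest2d(a, scale: int) -> Tensor:
    """Nearest-neighbour upsampling of the last two axes by integer ``scale``."""
    a = _as_tensor(a)
    data = a.data.repeat(scale, axis=-2).repeat(scale, axis=-1)

    def backward(g):
        if a.requires_grad:
            s = a.data.shape
            gg = g.reshape(s[:-2] + (s[-2], scale, s[-1], scale)).sum(axis=(-3, -1))
            a._accumulate(gg)

    return _make(data, (a,), backward)


def avg_pool2d(a, k: int) -> Tensor:
    """Non-overlapping k×k average pooling (spatial dims must divide by k)."""
    a = _as_tensor(a)
    *lead, H, W = a.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by pool size {k}")
    x = reshape(a, tuple(lead) + (H // k, k, W // k, k))
    return tmean(x, axis=(-3, -1))


def dwconv3x3(x, w, b) -> Tensor:
    """Fused depthwise 3×3 convolution, stride 1, zero padding 1.

    ``x``: (B, C, H, W); ``w``: (C, 3, 3); ``b``: (C,).  One graph node
    instead of the nine shifted multiply-adds it is equivalent to.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    data = np.einsum("bchwij,cij->bchw", win, w.data, optimize=True) \
        + b.data.reshape(1, C, 1, 1)

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bchwij,bchw->cij", win, g, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (1, 1), (1, 1)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, (3, 3), axis=(2, 3))
            wflip = w.data[:, ::-1, ::-1]
            x._accumulate(np.einsum("bchwij,cij->bchw", gwin, wflip, optimize=True))

    return _make(data, (x, w, b), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)
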