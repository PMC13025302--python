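"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the segmentation model needs: broadcasted
arithmetic, (batched) matmul, reshape/transpose/slice/concat, reductions,
exp/log/clip, fused softmax / layer-norm / GELU, a 3x3 unfold for the neck
convolution, and a decoupled-weight-decay Adam optimizer with a warmup+cosine
learning-rate schedule.  Gradients follow the standard chain-rule recurrences;
fused ops carry their analytic backward pass.

Everything is dtype-agnostic: float32 for model training, float64 for
finite-difference verification in the tests.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "add",
    "mul",
    "power",
    "matmul",
    "reshape",
    "transpose",
    "getitem",
    "concat",
    "pad",
    "tsum",
    "tmean",
    "exp",
    "log",
    "clip",
    "softmax",
    "layer_norm",
    "gelu",
    "unfold3x3",
    "AdamW",
    "warmup_cosine_lr",
]


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _backward: Callable | None = None,
    ):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents if requires_grad else ()
        self._backward = _backward if requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        # always copy on first set: the same upstream buffer may be routed to
        # several parents, and later in-place accumulation must not alias it
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-topological backward pass from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, Tensor(np.asarray(-1.0, dtype=self.dtype)))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce `grad` back to `shape` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents), _backward=backward if req else None)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data**exponent

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports numpy-style stacked (batched) operands."""
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _make(out_data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out_data = np.transpose(a.data, axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _make(out_data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def pad(a: Tensor, widths: Sequence[tuple[int, int]]) -> Tensor:
    """Zero-pad with per-axis (before, after) widths; backward crops."""
    out_data = np.pad(a.data, widths)
    crop = tuple(
        slice(b, b + s) for (b, _), s in zip(widths, a.data.shape)
    )

    def backward(g):
        a._accumulate(g[crop])

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions and pointwise nonlinearities
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            ga = np.broadcast_to(g, a.data.shape)
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            ga = np.broadcast_to(g, a.data.shape)
        a._accumulate(ga.astype(a.data.dtype, copy=True))

    return _make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is zero outside [lo, hi] (projection rule)."""
    out_data = np.clip(a.data, lo, hi)
    inside = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        a._accumulate(g * inside)

    return _make(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out_data = xhat * gain.data + bias.data

    def backward(g):
        if gain.requires_grad:
            red = tuple(range(g.ndim - 1))
            gain._accumulate((g * xhat).sum(axis=red))
            bias._accumulate(g.sum(axis=red))
        if a.requires_grad:
            gy = g * gain.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(inv * (gy - m1 - xhat * m2))

    return _make(out_data, (a, gain, bias), backward)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(a: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    x = a.data
    x2 = x * x
    inner = _GELU_C * (x + 0.044715 * x2 * x)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def backward(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x2)
        da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
        a._accumulate(g * da)

    return _make(out_data, (a,), backward)


def unfold3x3(a: Tensor) -> Tensor:
    """Gather the 3x3 neighborhood of every pixel of an (..., h, w, c) map.

    Returns (..., h, w, 9c) with zero padding at the border; the matmul of
    this against a (9c, c_out) weight is a same-padding 3x3 convolution.
    """
    *lead, h, w, c = a.data.shape
    widths = [(0, 0)] * len(lead) + [(1, 1), (1, 1), (0, 0)]
    padded = np.pad(a.data, widths)
    offsets = [(di, dj) for di in (0, 1, 2) for dj in (0, 1, 2)]
    cols = np.empty((*lead, h, w, 9, c), dtype=a.data.dtype)
    for k, (di, dj) in enumerate(offsets):
        cols[..., k, :] = padded[..., di : di + h, dj : dj + w, :]
    out_data = cols.reshape(*lead, h, w, 9 * c)

    def backward(g):
        gcols = g.reshape(*lead, h, w, 9, c)
        gpad = np.zeros_like(padded)
        for k, (di, dj) in enumerate(offsets):
            gpad[..., di : di + h, dj : dj + w, :] += gcols[..., k, :]
        a._accumulate(gpad[..., 1 : 1 + h, 1 : 1 + w, :])

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# modules and optimization
# ---------------------------------------------------------------------------

class Module:
    """Parameter container with recursive traversal."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Parameter):
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._collect_state(out, "")
        return out

    def _collect_state(self, out: dict, prefix: str) -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value.data
            elif isinstance(value, Module):
                value._collect_state(out, key + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._collect_state(out, f"{key}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        self._assign_state(state, "")

    def _assign_state(self, state: dict, prefix: str) -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                arr = np.asarray(state[key], dtype=value.data.dtype)
                if arr.shape != value.data.shape:
                    raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {value.data.shape}")
                value.data = arr
            elif isinstance(value, Module):
                value._assign_state(state, key + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v._assign_state(state, f"{key}.{i}.")


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * (update + self.weight_decay * p.data)
            else:
                p.data = p.data - self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def warmup_cosine_lr(step: int, total_steps: int, warmup_steps: int, base_lr: float) -> float:
    """Linear warmup to `base_lr`, then cosine decay to zero."""
    if total_steps <= 0:
        return base_lr
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    progress = min(max(step - warmup_steps, 0) / span, 1.0)
    return 0.5 * base_lr * (1.0 + math.cos(math.pi * progress))
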