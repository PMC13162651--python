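"""Minimal reverse-mode autodiff and neural-network layers on numpy.

The package trains small convolutional-transformer hybrids on CPU, so the
engine implements exactly the primitives those networks need: grouped /
depthwise 2-D convolution (im2col + einsum), linear maps, layer / batch
normalisation, softmax attention, the usual pointwise nonlinearities, an
AdamW optimiser and a cosine learning-rate schedule.

Conventions
-----------
* All tensors are float32 ``numpy`` arrays wrapped in :class:`Tensor`.
* FLOPs are counted as multiply-accumulate pairs x 2 (bias adds and
  pointwise ops ignored); enable with :func:`flop_counting`.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "ModuleList", "Sequential",
    "Conv2d", "Linear", "LayerNorm", "BatchNorm2d",
    "ReLU", "SiLU", "Sigmoid", "Identity",
    "AdamW", "cosine_lr",
    "relu", "silu", "sigmoid", "softmax", "layer_norm", "cross_entropy",
    "cat", "upsample_nearest", "global_avg_pool", "flop_counting",
    "flops_counted", "he_normal",
]

# ---------------------------------------------------------------------------
# FLOP accounting
# ---------------------------------------------------------------------------

_FLOPS = {"on": False, "count": 0}


@contextlib.contextmanager
def flop_counting():
    """Context manager: count MAC*2 FLOPs of conv/matmul ops executed inside."""
    prev_on, prev_count = _FLOPS["on"], _FLOPS["count"]
    _FLOPS["on"], _FLOPS["count"] = True, 0
    try:
        yield _FLOPS
    finally:
        _FLOPS["on"], _FLOPS["count"] = prev_on, prev_count


def flops_counted(state) -> int:
    return int(state["count"])


def _add_flops(n: int) -> None:
    if _FLOPS["on"]:
        _FLOPS["count"] += int(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self.name = name

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- autograd -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad) if grad is not None else np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ----------------------------------------------------------
    def _wrap(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(prev) if req else ())
        if req:
            out._backward = backward
        return out

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._wrap(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._wrap(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._wrap(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor(other) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._wrap(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._wrap(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._wrap(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._wrap(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.ascontiguousarray(g.transpose(inv)))

        return self._wrap(np.ascontiguousarray(self.data.transpose(axes)), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._wrap(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = self.data.argmax(axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(grad)

        return self._wrap(out_data, (self,), backward)

    def __getitem__(self, idx):
        """Basic (slice) indexing; gradients flow back into the sliced view."""
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                grad[idx] = g
                self._accum(grad)

        return self._wrap(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data
        a_sh, b_sh = self.shape, other.shape
        batch = int(np.prod(out_data.shape[:-2])) if out_data.ndim > 2 else 1
        _add_flops(2 * batch * a_sh[-2] * a_sh[-1] * b_sh[-1]
                   if self.ndim >= 2 else 2 * a_sh[-1] * b_sh[-1])

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, a_sh))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, b_sh))

        return self._wrap(out_data, (self, other), backward)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return x._wrap(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return x._wrap(s, (x,), backward)


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * s

    def backward(g):
        if x.requires_grad:
            x._accum(g * (s + x.data * s * (1.0 - s)))

    return x._wrap(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    return x._wrap(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learnable scale/shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    n = x.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gh = g * gamma.data
            dx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
            x._accum(dx.astype(np.float32))

    return x._wrap(out_data, (x, gamma, beta), backward)


def cat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(tensors) if req else ())
    if req:
        out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of a [B,C,H,W] map by an integer factor."""
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    B, C, H, W = x.shape

    def backward(g):
        if x.requires_grad:
            gr = g.reshape(B, C, H, factor, W, factor).sum(axis=(3, 5))
            x._accum(gr)

    return x._wrap(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """[B,C,H,W] -> [B,C] spatial mean."""
    return x.mean(axis=(2, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding=0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation. ``w``: [Cout, Cin/groups, kh, kw].

    ``padding`` is an int or an (pad_h, pad_w) pair.
    """
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    if Cin != Cg * groups:
        raise ValueError(f"conv2d channel mismatch: Cin={Cin}, weight expects {Cg * groups}")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = view[:, :, ::stride, ::stride]            # [B,Cin,Ho,Wo,kh,kw]
    cols_g = cols.reshape(B, groups, Cg, Ho, Wo, kh, kw)
    wg = w.data.reshape(groups, Cout // groups, Cg, kh, kw)
    out_data = np.einsum("bgchwij,gocij->bgohw", cols_g, wg, optimize=True)
    out_data = out_data.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    _add_flops(2 * B * Cout * Cg * kh * kw * Ho * Wo)

    prev = (x, w) if b is None else (x, w, b)

    def backward(g):
        gg = g.reshape(B, groups, Cout // groups, Ho, Wo)
        if w.requires_grad:
            dw = np.einsum("bgchwij,bgohw->gocij", cols_g, gg, optimize=True)
            w._accum(dw.reshape(Cout, Cg, kh, kw).astype(np.float32))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("gocij,bgohw->bgchwij", wg, gg, optimize=True)
            dcols = dcols.reshape(B, Cin, Ho, Wo, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        dcols[:, :, :, :, i, j]
            if ph or pw:
                dxp = dxp[:, :, ph:xp.shape[2] - ph, pw:xp.shape[3] - pw]
            x._accum(dxp.astype(np.float32))

    return x._wrap(out_data, prev, backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of [B,K] logits against integer labels."""
    labels = np.asarray(labels)
    B = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(B), labels].mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(B), labels] -= 1.0
            logits._accum((g * p / B).astype(np.float32))

    return logits._wrap(np.float32(loss), (logits,), backward)


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He (Kaiming) normal initialisation: N(0, sqrt(2/fan_in))."""
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._modules[key] = value
        object.__setattr__(self, key, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, items: Sequence[Module] = ()):
        super().__init__()
        self._items: list[Module] = []
        for m in items:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._items))] = m
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self._items:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size, stride: int = 1,
                 padding=0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        rng = rng or np.random.default_rng(0)
        fan_in = (in_ch // groups) * kh * kw
        self.weight = Parameter(he_normal(rng, (out_ch, in_ch // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(he_normal(rng, (out_dim, in_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class BatchNorm2d(Module):
    """Batch normalisation over (B,H,W) with running statistics."""

    def __init__(self, num_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_ch, dtype=np.float32))
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
        n = x.shape[0] * x.shape[2] * x.shape[3]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gh = g * gamma.data[None, :, None, None]
                if training:
                    mean_gh = gh.mean(axis=(0, 2, 3), keepdims=True)
                    mean_ghx = (gh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    dx = inv[None, :, None, None] * (gh - mean_gh - xhat * mean_ghx)
                else:
                    dx = gh * inv[None, :, None, None]
                x._accum(dx.astype(np.float32))
            _ = n

        return x._wrap(out_data, (x, gamma, beta), backward)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return silu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return sigmoid(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int, min_lr: float = 0.0) -> float:
    """Cosine learning-rate decay from ``base_lr`` to ``min_lr``."""
    if total_epochs <= 1:
        return base_lr
    t = min(epoch, total_epochs - 1) / (total_epochs - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * t))
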