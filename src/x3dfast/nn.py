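"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's feature volumes follow the (N, T, C, H, W) axis convention:
batch, frames, channels, height, width.  All layers in this module keep that
layout; 3D convolution therefore correlates over the T, H, W axes and mixes
the C axis.

The engine is deliberately small: tensors wrap float numpy arrays, every
operation records a closure that scatters the upstream gradient to its
parents, and ``Tensor.backward`` walks the graph in reverse topological
order.  Gradients are accumulated on *every* interior node of the graph,
which is what gradient-weighted class-activation mapping needs.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv3d",
    "BatchNorm",
    "Linear",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "SGD",
    "concat",
    "relu",
    "sigmoid",
    "softmax_cross_entropy",
    "no_grad",
    "set_seed",
    "get_rng",
    "ShapeError",
]


class ShapeError(ValueError):
    """Raised when tensor extents disagree with a layer's contract."""


# ---------------------------------------------------------------------------
# global state: gradient switch and the parameter-init / dropout RNG
# ---------------------------------------------------------------------------

_grad_enabled = True
_rng = np.random.default_rng(0)


def set_seed(seed: int) -> None:
    """Reset the global RNG driving parameter init and dropout masks."""
    global _rng
    _rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _rng


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helper ------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled:
            out._parents = parents
            out._backward = backward
        return out

    # -- introspection ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd -----------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other) -> "Tensor":
        o = self._coerce(other)
        a, b = self, o

        def back(g):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._op(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor._op(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        o = self._coerce(other)
        a, b = self, o

        def back(g):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._op(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * (self._coerce(other) ** -1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) * (self ** -1.0)

    def __pow__(self, exponent: float) -> "Tensor":
        a = self
        out_data = a.data ** exponent

        def back(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._op(out_data, (a,), back)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.shape
        return Tensor._op(
            a.data.reshape(shape), (a,), lambda g: a._accumulate(g.reshape(orig))
        )

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        a = self
        inv = np.argsort(axes)
        return Tensor._op(
            a.data.transpose(axes), (a,), lambda g: a._accumulate(g.transpose(inv))
        )

    def __getitem__(self, idx) -> "Tensor":
        a = self
        basic = isinstance(idx, (slice, int)) or (
            isinstance(idx, tuple) and all(isinstance(i, (slice, int)) for i in idx)
        )

        def back(g):
            full = np.zeros_like(a.data)
            if basic:
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._op(a.data[idx], (a,), back)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._op(out_data, (a,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -----------------------------------------
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor._op(a.data * mask, (a,), lambda g: a._accumulate(g * mask))

    def sigmoid(self) -> "Tensor":
        from scipy.special import expit

        a = self
        out_data = expit(a.data)
        return Tensor._op(
            out_data, (a,), lambda g: a._accumulate(g * out_data * (1.0 - out_data))
        )

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)
        return Tensor._op(out_data, (a,), lambda g: a._accumulate(g * out_data))

    def log(self) -> "Tensor":
        a = self
        return Tensor._op(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def back(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor._op(a.data @ b.data, (a, b), back)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    parents = tuple(tensors)
    sizes = [t.shape[axis] for t in parents]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(parents, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor._op(np.concatenate([t.data for t in parents], axis=axis), parents, back)


# ---------------------------------------------------------------------------
# 3D convolution over (N, T, C, H, W)
# ---------------------------------------------------------------------------


def _conv3d_out_extent(size: int, k: int, s: int, p: int) -> int:
    return (size + 2 * p - k) // s + 1


def conv3d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: tuple[int, int, int] = (1, 1, 1),
    padding: tuple[int, int, int] = (0, 0, 0),
    groups: int = 1,
) -> Tensor:
    """Cross-correlate ``x`` (N,T,C,H,W) with ``weight`` (C_out, C_in/g, kt, kh, kw).

    Implemented as a sum over kernel offsets of channel-mixing einsums; the
    backward pass mirrors the same loop, so no im2col buffer is ever
    materialized.
    """
    n, t, c, h, w = x.shape
    c_out, c_in_g, kt, kh, kw = weight.shape
    st, sh, sw = stride
    pt, ph, pw = padding
    if c != c_in_g * groups:
        raise ShapeError(
            f"conv3d expects {c_in_g * groups} input channels (groups={groups}), got {c}"
        )
    if c_out % groups:
        raise ShapeError(f"output channels {c_out} not divisible by groups {groups}")
    to = _conv3d_out_extent(t, kt, st, pt)
    ho = _conv3d_out_extent(h, kh, sh, ph)
    wo = _conv3d_out_extent(w, kw, sw, pw)
    if min(to, ho, wo) < 1:
        raise ShapeError(
            f"conv3d output collapses: input (T,H,W)=({t},{h},{w}), kernel ({kt},{kh},{kw})"
        )

    g_ = groups
    cog = c_out // g_
    xp = np.pad(x.data, ((0, 0), (pt, pt), (0, 0), (ph, ph), (pw, pw)))
    xg = xp.reshape(n, t + 2 * pt, g_, c_in_g, h + 2 * ph, w + 2 * pw)
    wg = weight.data.reshape(g_, cog, c_in_g, kt, kh, kw)

    out = np.zeros((n, to, g_, cog, ho, wo), dtype=x.dtype)
    offsets = [(dt, dh, dw) for dt in range(kt) for dh in range(kh) for dw in range(kw)]
    slices = {
        (dt, dh, dw): (
            slice(dt, dt + st * to, st),
            slice(dh, dh + sh * ho, sh),
            slice(dw, dw + sw * wo, sw),
        )
        for dt, dh, dw in offsets
    }
    for dt, dh, dw in offsets:
        ts, hs, ws = slices[(dt, dh, dw)]
        patch = xg[:, ts, :, :, hs, ws]
        out += np.einsum("ntgchw,goc->ntgohw", patch, wg[:, :, :, dt, dh, dw], optimize=True)
    out = out.reshape(n, to, c_out, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, 1, c_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def back(g):
        gg = g.reshape(n, to, g_, cog, ho, wo)
        # weight gradient
        gw = np.zeros_like(wg)
        for dt, dh, dw in offsets:
            ts, hs, ws = slices[(dt, dh, dw)]
            patch = xg[:, ts, :, :, hs, ws]
            gw[:, :, :, dt, dh, dw] = np.einsum(
                "ntgchw,ntgohw->goc", patch, gg, optimize=True
            )
        weight._accumulate(gw.reshape(weight.shape))
        # input gradient
        gxp = np.zeros_like(xg)
        for dt, dh, dw in offsets:
            ts, hs, ws = slices[(dt, dh, dw)]
            gxp[:, ts, :, :, hs, ws] += np.einsum(
                "ntgohw,goc->ntgchw", gg, wg[:, :, :, dt, dh, dw], optimize=True
            )
        gx = gxp.reshape(n, t + 2 * pt, c, h + 2 * ph, w + 2 * pw)
        x._accumulate(gx[:, pt : pt + t, :, ph : ph + h, pw : pw + w])
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 1, 3, 4)))

    return Tensor._op(out, parents, back)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Lightweight layer container with named parameters and buffers."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ----------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- mode ---------------------------------------------------------------
    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_bufs = dict(self.named_buffers())
        missing = (set(own_params) | set(own_bufs)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]} ...")
        for name, p in own_params.items():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape).copy()
        # buffers are plain arrays on their owning module; walk again to set
        for mod_prefix, mod in self._named_modules():
            for bname in getattr(mod, "_buffer_names", ()):
                key = mod_prefix + bname
                if key in state:
                    setattr(
                        mod,
                        bname,
                        np.asarray(state[key], dtype=getattr(mod, bname).dtype).copy(),
                    )

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._children():
            yield from child._named_modules(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ModuleList(list):
    """Plain list of modules, discovered by ``Module`` traversal."""


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(a) for a in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 extents, got {v!r}")
    return t


class Conv3d(Module):
    """3D convolution over (N,T,C,H,W) with 'same' or explicit padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel,
        stride=1,
        padding="same",
        groups: int = 1,
        bias: bool = False,
    ):
        super().__init__()
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        if padding == "same":
            if any(k % 2 == 0 for k in self.kernel):
                raise ValueError("'same' padding requires odd kernel extents")
            self.padding = tuple((k - 1) // 2 for k in self.kernel)
        else:
            self.padding = _triple(padding)
        self.groups = int(groups)
        if self.c_in % self.groups or self.c_out % self.groups:
            raise ShapeError(
                f"channels ({self.c_in}->{self.c_out}) not divisible by groups {self.groups}"
            )
        fan_in = (self.c_in // self.groups) * int(np.prod(self.kernel))
        std = math.sqrt(2.0 / fan_in)
        shape = (self.c_out, self.c_in // self.groups, *self.kernel)
        self.weight = Parameter(_rng.normal(0.0, std, size=shape))
        self.bias = Parameter(np.zeros(self.c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.c_in:
            raise ShapeError(
                f"Conv3d expects {self.c_in} channels, input has shape {x.shape}"
            )
        return conv3d(x, self.weight, self.bias, self.stride, self.padding, self.groups)

    def weight_count(self) -> int:
        """Number of kernel weights, excluding bias."""
        return int(self.weight.data.size)


class BatchNorm(Module):
    """Per-channel normalization over (N, T, H, W) for (N,T,C,H,W) inputs."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_channels = int(num_channels)
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels, dtype=np.float32)
        self.running_var = np.ones(num_channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.num_channels:
            raise ShapeError(
                f"BatchNorm expects {self.num_channels} channels, input has shape {x.shape}"
            )
        shape = (1, 1, self.num_channels, 1, 1)
        axes = (0, 1, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * inv
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True):
        super().__init__()
        self.c_in, self.c_out = int(c_in), int(c_out)
        bound = 1.0 / math.sqrt(c_in)
        self.weight = Parameter(_rng.uniform(-bound, bound, size=(c_in, c_out)))
        self.bias = Parameter(_rng.uniform(-bound, bound, size=(c_out,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.c_in:
            raise ShapeError(f"Linear expects {self.c_in} features, got {x.shape}")
        out = x.matmul(self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (_rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * Tensor(keep)


class SGD:
    """Stochastic gradient descent with optional momentum and weight decay."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float,
        momentum: float = 0.0,
        weight_decay: float = 0.0,
    ):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under softmax logits."""
    labels = np.asarray(labels)
    n, m = logits.shape
    if labels.shape != (n,):
        raise ShapeError(f"labels shape {labels.shape} does not match batch {n}")
    shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    logsumexp = shift.exp().sum(axis=1).log()
    picked = shift[np.arange(n), labels]
    return (logsumexp - picked).mean()
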