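"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the hierarchical attention network: dense
float64 tensors, the ops a BiLSTM-with-attention needs (matmul, broadcast
add/mul, tanh, sigmoid, slicing, row gather, concat, masked softmax,
log-softmax), and an Adam optimizer.  Gradients are validated against
numerical differentiation in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "concat",
    "take_rows",
    "masked_softmax",
    "log_softmax",
    "backward",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- operator sugar --
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul_scalar(_wrap(other), -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, float(other))
        return mul(self, other)

    def __rmul__(self, other):
        return self.__mul__(other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


def tensor(data) -> Tensor:
    """A constant (non-trainable) graph leaf."""
    return _wrap(data)


def parameter(data) -> Tensor:
    """A trainable graph leaf."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bw)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def bw(g):
        _accum(a, g * s)

    return Tensor(a.data * s, parents=(a,), backward_fn=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            _accum(a, g @ b.data.T)
        if b.requires_grad:
            _accum(b, a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward_fn=bw)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def bw(g):
        _accum(a, g * (1.0 - y * y))

    return Tensor(y, parents=(a,), backward_fn=bw)


def sigmoid(a: Tensor) -> Tensor:
    y = expit(a.data)

    def bw(g):
        _accum(a, g * y * (1.0 - y))

    return Tensor(y, parents=(a,), backward_fn=bw)


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            _accum(a, ga)

    return Tensor(out_data, parents=(a,), backward_fn=bw)


def take_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows by integer index (duplicates allowed)."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            _accum(a, ga)

    return Tensor(out_data, parents=(a,), backward_fn=bw)


def concat(parts: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(p, g[tuple(sl)])

    return Tensor(out_data, parents=tuple(parts), backward_fn=bw)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = a.data.reshape(shape)

    def bw(g):
        _accum(a, g.reshape(a.data.shape))

    return Tensor(out_data, parents=(a,), backward_fn=bw)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward_fn=bw)


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` with False-masked positions excluded (weight 0).

    Masked positions receive exactly zero probability and transmit no
    gradient, so attention normalization holds over the true positions only.
    """
    m = np.asarray(mask, dtype=bool)
    x = np.where(m, scores.data, -np.inf)
    x_max = np.max(x, axis=axis, keepdims=True)
    x_max = np.where(np.isfinite(x_max), x_max, 0.0)
    e = np.exp(x - x_max)
    denom = e.sum(axis=axis, keepdims=True)
    y = np.where(m, e / np.where(denom == 0, 1.0, denom), 0.0)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(scores, y * (g - dot))

    return Tensor(y, parents=(scores,), backward_fn=bw)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data
    x_max = x.max(axis=axis, keepdims=True)
    lse = x_max + np.log(np.exp(x - x_max).sum(axis=axis, keepdims=True))
    y = x - lse

    def bw(g):
        soft = np.exp(y)
        _accum(a, g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor(y, parents=(a,), backward_fn=bw)


def lstm_preact(x: Tensor, Wx: Tensor, h: Tensor, Wh: Tensor, b: Tensor) -> Tensor:
    """Fused LSTM input pre-activation ``x @ Wx + h @ Wh + b``."""
    out_data = x.data @ Wx.data + h.data @ Wh.data + b.data

    def bw(g):
        if x.requires_grad:
            _accum(x, g @ Wx.data.T)
        if Wx.requires_grad:
            _accum(Wx, x.data.T @ g)
        if h.requires_grad:
            _accum(h, g @ Wh.data.T)
        if Wh.requires_grad:
            _accum(Wh, h.data.T @ g)
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(x, Wx, h, Wh, b), backward_fn=bw)


def lstm_cell(
    z: Tensor, h_prev: Tensor, c_prev: Tensor, mask: np.ndarray
) -> tuple[Tensor, Tensor]:
    """Fused LSTM cell with step masking.

    ``z`` is the pre-activation (B, 4H) in gate order [input, forget, cell,
    output]; ``mask`` is (B, 1) with 0 rows carrying the previous state
    through unchanged.  Returns (h, c).  The two outputs propagate their
    gradient contributions independently, which is valid because backprop
    is linear in the output gradients.
    """
    B, four_h = z.shape
    H = four_h // 4
    zd = z.data
    i = expit(zd[:, :H])
    f = expit(zd[:, H : 2 * H])
    g = np.tanh(zd[:, 2 * H : 3 * H])
    o = expit(zd[:, 3 * H :])
    c_new = f * c_prev.data + i * g
    tc = np.tanh(c_new)
    h_new = o * tc
    m = np.asarray(mask, dtype=float)
    h_data = m * h_new + (1.0 - m) * h_prev.data
    c_data = m * c_new + (1.0 - m) * c_prev.data

    def common(dc_new: np.ndarray, do: np.ndarray) -> None:
        dz = np.empty_like(zd)
        dz[:, :H] = dc_new * g * i * (1.0 - i)
        dz[:, H : 2 * H] = dc_new * c_prev.data * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = dc_new * i * (1.0 - g * g)
        dz[:, 3 * H :] = do * o * (1.0 - o)
        _accum(z, dz)
        _accum(c_prev, dc_new * f)

    def bw_h(dh):
        dh_m = dh * m
        do = dh_m * tc
        dc_new = dh_m * o * (1.0 - tc * tc)
        common(dc_new, do)
        _accum(h_prev, dh * (1.0 - m))

    def bw_c(dc):
        dc_m = dc * m
        common(dc_m, np.zeros_like(dc_m))
        _accum(c_prev, dc * (1.0 - m))

    parents = (z, h_prev, c_prev)
    h_out = Tensor(h_data, parents=parents, backward_fn=bw_h)
    c_out = Tensor(c_data, parents=parents, backward_fn=bw_c)
    return h_out, c_out


def attn_pool(h_all: Tensor, alpha: Tensor, T: int, B: int) -> Tensor:
    """Attention-weighted state sum: with ``h_all`` the timestep-major
    (T*B, D) stack and ``alpha`` the (T, B) weights, returns
    ``out[b] = sum_t alpha[t, b] * h_all[t*B + b]``."""
    D = h_all.shape[1]
    hr = h_all.data.reshape(T, B, D)
    a = alpha.data
    out_data = np.einsum("tb,tbd->bd", a, hr)

    def bw(g):
        if h_all.requires_grad:
            _accum(h_all, (a[:, :, None] * g[None, :, :]).reshape(T * B, D))
        if alpha.requires_grad:
            _accum(alpha, np.einsum("tbd,bd->tb", hr, g))

    return Tensor(out_data, parents=(h_all, alpha), backward_fn=bw)


def backward(root: Tensor) -> None:
    """Reverse-mode sweep from ``root`` (summed if non-scalar)."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
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
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (
                mh / (np.sqrt(vh) + self.eps) + self.weight_decay * p.data
            )
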