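"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core that the vision-transformer backbone, the
self-distillation pretraining loop and the fine-tuning harness are built on.
It implements exactly the operator set those models need (broadcast-aware
arithmetic, batched matmul, softmax / log-softmax, GELU, layer statistics,
reshapes, slicing, concatenation) plus an Adam optimizer.

Everything is float64 and single-threaded NumPy, so identical seeds give
bit-identical training trajectories on one CPU thread.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Adam", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._node(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return self._node(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)
        out_data = a.data ** p

        def bwd(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return self._node(out_data, (a,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return self._node(np.matmul(a.data, b.data), (a, b), bwd)

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return self._node(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._node(np.log(a.data), (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data ** 2))

        return self._node(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                            np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return self._node(out_data, (a,), bwd)

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bwd(g):
            if a.requires_grad:
                sig = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                               np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
                a._accum(g * sig)

        return self._node(out_data, (a,), bwd)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * phi

        def bwd(g):
            if a.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                a._accum(g * (phi + x * pdf))

        return self._node(out_data, (a,), bwd)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(ax % a.ndim for ax in axes):
                    gg = np.expand_dims(gg, ax)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._node(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- softmax family --------------------------------------------------------

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accum(out_data * (g - dot))

        return self._node(out_data, (a,), bwd)

    def log_softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return self._node(out_data, (a,), bwd)

    # -- shape manipulation ----------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old_shape = a.shape

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(old_shape))

        return self._node(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))

        def bwd(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return self._node(a.data.transpose(axes), (a,), bwd)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(np.swapaxes(g, ax1, ax2))

        return self._node(np.swapaxes(a.data, ax1, ax2), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros(a.shape, dtype=np.float64)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._node(a.data[idx], (a,), bwd)

    # -- backward pass ----------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this node to all ancestors."""
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
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._node(data, tensors, bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    data = np.stack([t.data for t in tensors], axis=axis)
    return Tensor._node(data, tensors, bwd)


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 weight_decay: float = 0.0, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = None):
        self.params = params
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params.values() if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params.values():
                    if p.grad is not None:
                        p.grad *= scale
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.asarray(v, dtype=np.float64) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v, dtype=np.float64) for k, v in state["v"].items()}
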