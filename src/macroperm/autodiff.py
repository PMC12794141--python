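"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the permeability models need: dense affine
maps, ReLU/sigmoid/softmax/log/exp, concatenation, row gather and segment
(scatter-add) reduction for message passing, and scalar reductions for losses.
Gradients flow through a topologically sorted tape; everything is float64 and
deterministic given the op sequence, which is what makes bit-identical
checkpoint reloads and same-seed reruns possible.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_mean",
    "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference paths)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over broadcast axes so it matches the original shape."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # ---- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # release the graph: the backward closures reference their output
        # tensors (a cycle), so break them eagerly instead of waiting for gc
        for node in topo:
            node._backward = None
            node._parents = ()

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(p for p in parents)
            out._backward = backward(out)
        return out

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        data = self.data + other.data

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.data.shape))
            return run

        return self._make(data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(-out.grad)
            return run

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        data = self.data * other.data

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))
            return run

        return self._make(data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        data = self.data / other.data

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad / other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                    )
            return run

        return self._make(data, (self, other), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        data = self.data @ other.data

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ out.grad)
            return run

        return self._make(data, (self, other), bw)

    __matmul__ = matmul

    # ---- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * mask)
            return run

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self) -> "Tensor":
        # numerically stable both tails
        s = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -500, None))),
            np.exp(np.clip(self.data, None, 500))
            / (1.0 + np.exp(np.clip(self.data, None, 500))),
        )

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * s * (1.0 - s))
            return run

        return self._make(s, (self,), bw)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * sign)
            return run

        return self._make(np.abs(self.data), (self,), bw)

    def log(self) -> "Tensor":
        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad / self.data)
            return run

        return self._make(np.log(self.data), (self,), bw)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * e)
            return run

        return self._make(e, (self,), bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(out):
            def run():
                if self.requires_grad:
                    dot = (out.grad * s).sum(axis=axis, keepdims=True)
                    self._accumulate(s * (out.grad - dot))
            return run

        return self._make(s, (self,), bw)

    def clip_probs(self, eps: float = 1e-7) -> "Tensor":
        """Clamp into (eps, 1-eps); gradient passes through the interior only."""
        mask = (self.data > eps) & (self.data < 1.0 - eps)
        data = np.clip(self.data, eps, 1.0 - eps)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * mask)
            return run

        return self._make(data, (self,), bw)

    # ---- shape ops ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(out):
            def run():
                if self.requires_grad:
                    g = out.grad
                    if axis is not None and not keepdims:
                        g = np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            return run

        return self._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        data = self.data.reshape(*shape)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad.reshape(self.data.shape))
            return run

        return self._make(data, (self,), bw)

    def transpose(self) -> "Tensor":
        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad.T)
            return run

        return self._make(self.data.T, (self,), bw)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        data = self.data[:, start:stop]

        def bw(out):
            def run():
                if self.requires_grad:
                    g = np.zeros_like(self.data)
                    g[:, start:stop] = out.grad
                    self._accumulate(g)
            return run

        return self._make(data, (self,), bw)


class Parameter(Tensor):
    """A trainable tensor (requires_grad always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def run():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * data.ndim
                    idx[axis] = slice(a, b)
                    t._accumulate(out.grad[tuple(idx)])

        out._backward = run
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows x[index]; backward scatter-adds into the source rows."""
    index = np.asarray(index, dtype=np.int64)
    data = x.data[index]

    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and x.requires_grad
    if out.requires_grad:
        out._parents = (x,)

        def run():
            g = np.zeros_like(x.data)
            np.add.at(g, index, out.grad)
            x._accumulate(g)

        out._backward = run
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of x into ``n_segments`` buckets; backward gathers per row."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, x.data)

    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and x.requires_grad
    if out.requires_grad:
        out._parents = (x,)

        def run():
            x._accumulate(out.grad[segment_ids])

        out._backward = run
    return out


def segment_mean(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    counts = np.bincount(segment_ids, minlength=n_segments).astype(np.float64)
    counts[counts == 0.0] = 1.0
    total = segment_sum(x, segment_ids, n_segments)
    return total * (1.0 / counts)[:, None]


class Adam:
    """Adam optimizer over a flat list of Parameters (deterministic)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
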