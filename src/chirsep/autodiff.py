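"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

Just enough machinery for the dual-stream attention network: broadcast-aware
elementwise arithmetic, matmul, reductions, softmax, layer normalisation and
an Adam optimiser.  All computation is plain numpy, so results are bit-for-bit
reproducible on a fixed seed and a single thread.  Gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(k for k, s in enumerate(shape) if s == 1 and grad.shape[k] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._accumulate(g)
            b._accumulate(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._accumulate(g * b.data)
            b._accumulate(g * a.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._accumulate(g / b.data)
            b._accumulate(-g * a.data / b.data ** 2)

        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g, a=self, p=exponent):
            a._accumulate(g * p * a.data ** (p - 1))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accumulate(ga)
            b._accumulate(gb)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, y=out_data):
            a._accumulate(g * y)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accumulate(g / a.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, y=out_data):
            a._accumulate(g * (1.0 - y ** 2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            a._accumulate(g * m)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = np.where(self.data >= 0,
                            1.0 / (1.0 + np.exp(-np.abs(self.data))),
                            np.exp(-np.abs(self.data))
                            / (1.0 + np.exp(-np.abs(self.data))))

        def backward(g, a=self, y=out_data):
            a._accumulate(g * y * (1.0 - y))

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g, a=self, s=sign):
            a._accumulate(g * s)

        return self._make(np.abs(self.data), (self,), backward)

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g, a=self, s=orig):
            a._accumulate(g.reshape(s))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        def backward(g, a=self, x=a1, y=a2):
            a._accumulate(np.swapaxes(g, x, y))

        return self._make(np.swapaxes(self.data, a1, a2), (self,), backward)

    def squeeze(self, axis: int):
        orig = self.data.shape

        def backward(g, a=self, s=orig):
            a._accumulate(g.reshape(s))

        return self._make(np.squeeze(self.data, axis=axis), (self,), backward)

    # -- fused primitives ---------------------------------------------------
    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, out=y, ax=axis):
            dot = (g * out).sum(axis=ax, keepdims=True)
            a._accumulate(out * (g - dot))

        return self._make(y, (self,), backward)

    def layer_norm(self, axis: int = -1, eps: float = 1e-5):
        """Normalise to zero mean / unit variance along ``axis`` (no affine)."""
        mu = self.data.mean(axis=axis, keepdims=True)
        var = self.data.var(axis=axis, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = (self.data - mu) * inv

        def backward(g, a=self, out=y, istd=inv, ax=axis):
            n = a.data.shape[ax]
            gm = g.mean(axis=ax, keepdims=True)
            gym = (g * out).mean(axis=ax, keepdims=True)
            a._accumulate(istd * (g - gm - out * gym))

        return self._make(y, (self,), backward)

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g, parts=tuple(tensors), offs=offsets, ax=axis):
            for t, lo, hi in zip(parts, offs[:-1], offs[1:]):
                idx = [slice(None)] * g.ndim
                idx[ax] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

        out._parents = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adam optimiser over a dict of parameter Tensors (optionally filtered)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 trainable: set[str] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.trainable = set(params) if trainable is None else set(trainable)
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for name in self.trainable:
            p = self.params[name]
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g ** 2
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
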