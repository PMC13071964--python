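"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps an
``ndarray`` and records the closure that propagates its output gradient to
its parents.  Only the operations the lung-sound network needs are
implemented (dense algebra, shape surgery, a handful of activations); each
op carries its analytic vector-Jacobian product and is validated against
finite differences in the test suite.

Gradient buffers are ownership-aware: a backward closure marks the arrays it
freshly allocated (``fresh=True``) so accumulation can take them without a
defensive copy, while pass-through gradients (residual adds, reshapes that
alias) are copied to prevent two nodes sharing one buffer.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "layer_norm", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape.

    Returns ``grad`` itself (not fresh) when no reduction is needed.
    """
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _is_basic_index(idx) -> bool:
    """True when ``idx`` uses only slices/ints/ellipsis (no repeats possible)."""
    if isinstance(idx, tuple):
        return all(isinstance(i, (slice, int, type(Ellipsis), type(None))) for i in idx)
    return isinstance(idx, (slice, int, type(Ellipsis)))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray, fresh: bool = False):
        if self.grad is None:
            self.grad = g if fresh else g.copy()
        else:
            self.grad += g

    def _acc_unbroadcast(self, g: np.ndarray, fresh: bool = False):
        red = _unbroadcast(g, self.data.shape)
        self._accumulate(red, fresh=fresh or red is not g)

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._acc_unbroadcast(g)
            if other.requires_grad:
                other._acc_unbroadcast(g)

        return Tensor._from_op(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accumulate(-g, fresh=True)

        return Tensor._from_op(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._acc_unbroadcast(g * other.data, fresh=True)
            if other.requires_grad:
                other._acc_unbroadcast(g * self.data, fresh=True)

        return Tensor._from_op(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._acc_unbroadcast(g / other.data, fresh=True)
            if other.requires_grad:
                other._acc_unbroadcast(-g * self.data / other.data**2, fresh=True)

        return Tensor._from_op(self.data / other.data, (self, other), back)

    def __pow__(self, exponent: float):
        def back(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1), fresh=True)

        return Tensor._from_op(self.data**exponent, (self,), back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim > 2 and b.ndim == 2:
                    ga = g @ b.T
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._acc_unbroadcast(ga, fresh=True)
            if other.requires_grad:
                if b.ndim == 2 and a.ndim > 2:
                    # dense-layer path: collapse the batch axes once
                    gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                    other._accumulate(gb, fresh=True)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                    other._acc_unbroadcast(gb, fresh=True)

        return Tensor._from_op(self.data @ other.data, (self, other), back)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy(), fresh=True)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape surgery -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def back(g):
            if self.requires_grad:
                self._accumulate(np.ascontiguousarray(g.transpose(inv)), fresh=True)

        return Tensor._from_op(self.data.transpose(axes), (self,), back)

    def __getitem__(self, idx):
        basic = _is_basic_index(idx)

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accumulate(full, fresh=True)

        return Tensor._from_op(self.data[idx], (self,), back)

    def pad2d(self, pad_h: int, pad_w: int, axes: tuple[int, int]):
        """Zero-pad ``pad_h``/``pad_w`` on both sides of the two given axes."""
        widths = [(0, 0)] * self.ndim
        widths[axes[0]] = (pad_h, pad_h)
        widths[axes[1]] = (pad_w, pad_w)
        sl = tuple(slice(w[0], s + w[0]) for w, s in zip(widths, self.data.shape))

        def back(g):
            if self.requires_grad:
                self._accumulate(np.ascontiguousarray(g[sl]), fresh=True)

        return Tensor._from_op(np.pad(self.data, widths), (self,), back)

    def roll(self, shifts, axes):
        def back(g):
            if self.requires_grad:
                neg = tuple(-s for s in shifts) if isinstance(shifts, tuple) else -shifts
                self._accumulate(np.roll(g, neg, axis=axes), fresh=True)

        return Tensor._from_op(np.roll(self.data, shifts, axis=axes), (self,), back)

    # -- nonlinearities ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * out_data, fresh=True)

        return Tensor._from_op(out_data, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accumulate(g / self.data, fresh=True)

        return Tensor._from_op(np.log(self.data), (self,), back)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s), fresh=True)

        return Tensor._from_op(s, (self,), back)

    def gelu(self):
        # exact (erf) form; derivative = Phi(x) + x * phi(x)
        x = self.data
        phi_cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * phi_cdf

        def back(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accumulate(g * (phi_cdf + x * pdf), fresh=True)

        return Tensor._from_op(out_data, (self,), back)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def back(g):
            if self.requires_grad:
                self._accumulate(g * (s * (1.0 + self.data * (1.0 - s))), fresh=True)

        return Tensor._from_op(out_data, (self,), back)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot), fresh=True)

        return Tensor._from_op(y, (self,), back)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(np.ascontiguousarray(g[tuple(sl)]), fresh=True)

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), back)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * weight.data + bias.data

    def back(g):
        if weight.requires_grad:
            axes = tuple(range(g.ndim - 1))
            weight._accumulate((g * xhat).sum(axis=axes), fresh=True)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=tuple(range(g.ndim - 1))), fresh=True)
        if x.requires_grad:
            dxhat = g * weight.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2), fresh=True)

    return Tensor._from_op(out_data, (x, weight, bias), back)
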