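"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` replays the tape in reverse topological order.  The op set is
exactly what the package's networks need (dense/conv/batch-norm layers and
graph convolutions): elementwise arithmetic with broadcasting, matmul
(including stacked batches), relu/sigmoid/sqrt/log/exp, axis reductions,
reshape/transpose, and an im2col gather for 1-D convolution.

Gradient correctness is enforced by finite-difference tests rather than by
construction, so keep new ops paired with a test.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "im2col1d", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:  # keep float32, promote the rest
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep tapes would overflow recursion
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
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, grad):
        # Adopt the incoming array; never mutate it in place.  Safe because
        # reverse-topological order guarantees a node's grad is complete
        # before its own backward runs, so adopted arrays are final.
        if self.requires_grad:
            if self.grad is None:
                self.grad = grad
            else:
                self.grad = self.grad + grad

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, self._coerce(other)

        def bw(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._from_op(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._coerce(other)

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(g * p * np.power(a.data, p - 1))

        return Tensor._from_op(np.power(a.data, p), (a,), bw)

    def __matmul__(self, other):
        a, b = self, self._coerce(other)
        # fast path: stacked batch on the left, plain matrix on the right —
        # flatten to one large BLAS call instead of per-item small ones
        fast = a.ndim > 2 and b.ndim == 2

        if fast:
            lead = a.data.shape[:-1]
            out = (a.data.reshape(-1, a.data.shape[-1]) @ b.data).reshape(
                *lead, b.data.shape[1]
            )
        else:
            out = a.data @ b.data

        def bw(g):
            if fast:
                g2 = g.reshape(-1, g.shape[-1])
                a._accum((g2 @ b.data.T).reshape(a.shape))
                b._accum(a.data.reshape(-1, a.data.shape[-1]).T @ g2)
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
                a._accum(_unbroadcast(ga, a.shape))
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(out, (a, b), bw)

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._from_op(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
        return Tensor._from_op(out, (a,), lambda g: a._accum(g * out * (1 - out)))

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor._from_op(out, (a,), lambda g: a._accum(g * (1 - out * out)))

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._from_op(out, (a,), lambda g: a._accum(g * out))

    def log(self):
        a = self
        return Tensor._from_op(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        return self ** 0.5

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        a = self
        return Tensor._from_op(
            a.data.reshape(*shape), (a,), lambda g: a._accum(g.reshape(a.shape))
        )

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)
        return Tensor._from_op(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape))

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def im2col1d(x: Tensor, kernel: int, stride: int = 1, pad: int | None = None) -> Tensor:
    """Gather sliding patches of a (N, C, L) tensor into (N, L_out, C*k).

    Zero padding defaults to the 'same' amount for stride 1 (total k-1,
    split left-heavy-right as (k-1)//2 / k//2).
    """
    n, c, L = x.shape
    if pad is None:
        pad = kernel - 1
    pl, pr = pad // 2, pad - pad // 2
    padded = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    Lp = L + pl + pr
    L_out = (Lp - kernel) // stride + 1
    # stack the k shifted views: (N, C, L_out, k)
    patches = np.stack(
        [padded[:, :, j: j + stride * L_out: stride] for j in range(kernel)],
        axis=3,
    )
    out = np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(
        n, L_out, c * kernel
    )

    def bw(g):
        gp = g.reshape(n, L_out, c, kernel).transpose(0, 2, 1, 3)
        gpad = np.zeros((n, c, Lp), dtype=g.dtype)
        for j in range(kernel):  # scatter-add per kernel offset
            gpad[:, :, j: j + stride * L_out: stride] += gp[:, :, :, j]
        x._accum(gpad[:, :, pl: pl + L])

    return Tensor._from_op(out, (x,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._from_op(np.concatenate(datas, axis=axis), tensors, bw)
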