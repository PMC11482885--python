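"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The encoders and pre-training objectives in this package are small enough that a
compact tape-based engine is sufficient: a :class:`Tensor` wraps an ``ndarray``,
records its parents, and ``backward()`` replays the tape in reverse topological
order.  Broadcasting is handled by summing gradients over broadcast axes.  The
one non-elementwise primitive that matters — the first-order linear recurrence
``h_t = a_t * h_{t-1} + b_t`` used by the state-space scan — carries a
hand-derived adjoint (a reverse-direction linear recurrence), so sequences do
not unroll into thousands of tape nodes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "linear_recurrence", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev_state = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev_state
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = (
            requires_grad or any(p.requires_grad for p in _prev)
        ) and _GRAD_ENABLED[0]
        self._backward = None
        self._prev = _prev if self.requires_grad else ()

    # ---- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit gradient")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if node._prev:
                # intermediate gradients are no longer needed once propagated;
                # dropping the closure and parent links also breaks the
                # out<->closure reference cycle so the graph is freed promptly
                node.grad = None
                node._backward = None
                node._prev = ()

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw():
            g = out.grad
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga.reshape(self.shape) if ga.shape != self.shape and ga.size == self.data.size else ga, self.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out

    # ---- elementwise non-linearities ------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        out._backward = _bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        out._backward = _bw
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (s * (1.0 + self.data * (1.0 - s))))

        out._backward = _bw
        return out

    def softplus(self):
        # numerically stable log(1+exp(x))
        out = Tensor(np.logaddexp(0.0, self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / (1.0 + np.exp(-self.data)))

        out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _bw
        return out

    # ---- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _bw
        return out

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
        return out

    @staticmethod
    def concatenate(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _bw():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(out.grad[tuple(sl)])

        out._backward = _bw
        return out


def linear_recurrence(a: Tensor, b: Tensor) -> Tensor:
    """First-order linear recurrence along axis 1.

    Computes ``h[:, t] = a[:, t] * h[:, t-1] + b[:, t]`` with ``h[:, -1] = 0``
    for arrays of shape ``(batch, L, ...)``.  The adjoint is the reverse
    recurrence ``lam_t = g_t + a_{t+1} * lam_{t+1}`` with ``dL/db_t = lam_t``
    and ``dL/da_t = lam_t * h_{t-1}``.
    """
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    A, B = a.data, b.data
    if A.shape != B.shape:
        raise ValueError("coefficient and input arrays must share a shape")
    L = A.shape[1]
    h = np.empty_like(B)
    acc = np.zeros(A.shape[:1] + A.shape[2:])
    for t in range(L):
        acc = A[:, t] * acc + B[:, t]
        h[:, t] = acc
    out = Tensor(h, _prev=(a, b))

    def _bw():
        g = out.grad
        lam = np.zeros(A.shape[:1] + A.shape[2:])
        da = np.empty_like(A) if a.requires_grad else None
        db = np.empty_like(B) if b.requires_grad else None
        for t in range(L - 1, -1, -1):
            if t + 1 < L:
                lam = g[:, t] + A[:, t + 1] * lam
            else:
                lam = g[:, t].copy()
            if db is not None:
                db[:, t] = lam
            if da is not None:
                da[:, t] = lam * (h[:, t - 1] if t > 0 else 0.0)
        if a.requires_grad:
            a._accum(da)
        if b.requires_grad:
            b._accum(db)

    out._backward = _bw
    return out
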