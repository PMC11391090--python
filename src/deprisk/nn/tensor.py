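"""Reverse-mode automatic differentiation over NumPy arrays.

A minimal define-by-run tape: each :class:`Tensor` wraps a float64
``ndarray`` and remembers how it was produced, so ``loss.backward()`` can
accumulate gradients into every parameter that requested them.  All
arithmetic is float64 throughout, which keeps forward passes bit-reproducible
on one machine and makes finite-difference gradient checks meaningful.

Only the operations the encoders in this package need are implemented:
broadcast arithmetic, matmul, reductions, slicing/concatenation, the usual
pointwise nonlinearities, an embedding gather, and a numerically stable
binary cross-entropy on logits.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # non-inplace: `grad` may be a view into a consumer's gradient
        self.grad = grad if self.grad is None else self.grad + grad

    # -- misc -----------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(out):
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out.data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(out):
            if self.requires_grad:
                expanded = out.data if keepdims else np.expand_dims(out.data, axis)
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                mask = self.data == expanded
                counts = mask.sum(axis=axis, keepdims=True)
                self._accum(mask * g / counts)

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a, b):
        out_data = np.swapaxes(self.data, a, b)

        def backward(out):
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes):
        out_data = np.transpose(self.data, axes)
        inv = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accum(np.transpose(out.grad, inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        # iterative topological sort (graphs can be thousands of nodes deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)


# -- free functions -----------------------------------------------------------


def concatenate(tensors, axis: int) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    return Tensor._make(out_data, tensors, backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(out):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(out.grad, i, axis=axis))

    return Tensor._make(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (fused forward + backward)."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(out):
        if x.requires_grad:
            inner = (out.grad * out.data).sum(axis=axis, keepdims=True)
            x._accum(out.data * (out.grad - inner))

    return Tensor._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Normalize the last axis to zero mean / unit (biased) variance, then
    scale and shift.  Fused: one graph node instead of a dozen."""
    d = x.data.shape[-1]
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv_std
    out_data = xhat * gamma.data + beta.data

    def backward(out):
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, d).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, d).sum(axis=0))
        if x.requires_grad:
            gh = g * gamma.data  # dL/dxhat
            term = gh - gh.mean(axis=-1, keepdims=True) \
                - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv_std * term)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Gather rows `ids` from a (V, d) weight matrix."""
    ids = np.asarray(ids)
    out_data = weight.data[ids]

    def backward(out):
        if weight.requires_grad:
            g = np.zeros_like(weight.data)
            np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, weight.data.shape[-1]))
            weight._accum(g)

    return Tensor._make(out_data, (weight,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits.

    Uses the softplus identity ``max(z,0) - z*y + log1p(exp(-|z|))`` so the
    loss is finite for any logit; the gradient is ``(sigmoid(z) - y) / n``.
    """
    targets = np.asarray(targets, dtype=np.float64)
    z = logits.data
    per = np.maximum(z, 0.0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    out_data = per.mean()

    def backward(out):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accum(out.grad * (s - targets) / z.size)

    return Tensor._make(out_data, (logits,), backward)
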