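"""Minimal reverse-mode automatic differentiation on numpy arrays.

Tensors are float64 throughout: the package's oracle tests compare against
explicit-loop evaluations at 1e-8..1e-10 and double precision keeps those
comparisons honest. The networks in this package are small (a few layers,
feature widths in the tens to hundreds), so no effort is spent on kernels,
fusion or memory reuse — only on correctness of the vector-Jacobian
products, which are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape metadata needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _track(self, *parents: "Tensor") -> bool:
        return any(p.requires_grad or p._parents for p in parents)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data
        if not self._track(self, other):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor(out_data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        if not self._track(self):
            return Tensor(-self.data)

        def backward(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        if not self._track(self, other):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Tensor(out_data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, exponent: float):
        out_data = self.data**exponent
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, parents=(self,), backward=backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        if not self._track(self, other):
            return Tensor(out_data)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accumulate(g * b)
                other._accumulate(g * a)
                return
            if a.ndim == 1:
                a2 = a[None, :]
                ga = (g[None, :] @ np.swapaxes(b, -1, -2))[0]
                gb = a2.T @ g[None, :] if b.ndim == 2 else np.swapaxes(a2, -1, -2) @ g[None, :]
                self._accumulate(ga)
                other._accumulate(_unbroadcast(gb, b.shape))
                return
            if b.ndim == 1:
                ga = g[..., :, None] @ b[None, :]
                gb = np.swapaxes(a, -1, -2) @ g[..., :, None]
                self._accumulate(_unbroadcast(ga, a.shape))
                other._accumulate(_unbroadcast(gb[..., 0], b.shape))
                return
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    # -- elementwise nonlinearities ---------------------------------------

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g * (self.data > 0.0))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sigmoid(self):
        out_data = expit(self.data)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=backward)

    def exp(self):
        out_data = np.exp(self.data)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self):
        out_data = np.log(self.data)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def softplus(self):
        """log(1 + e^x), computed without overflow; gradient is sigmoid(x)."""
        out_data = np.logaddexp(0.0, self.data)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g * expit(self.data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return Tensor(out_data, parents=(self,), backward=backward)

    # -- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(out_data, parents=(self,), backward=backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, parents=(self,), backward=backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=backward)

    def take_rows(self, indices: np.ndarray):
        """Row lookup (embedding gather): self[indices] along axis 0."""
        idx = np.asarray(indices)
        out_data = self.data[idx]
        if not self._track(self):
            return Tensor(out_data)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=backward)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad or t._parents for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad or t._parents for t in tensors):
        return Tensor(out_data)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with bias correction; the package-wide default optimizer."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
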