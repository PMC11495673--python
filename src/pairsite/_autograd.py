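"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`pairsite.model_core` is small (tens of residues per
protein, hidden widths in the tens), so a compact tape-based engine in
float64 is both fast enough and exactly reproducible across runs.  Only the
operations the model needs are provided: broadcasting arithmetic, matmul,
elementwise nonlinearities, row gather, segment-sum (for message passing
over edge lists), concatenation, reductions, and a numerically stable
sigmoid/binary-cross-entropy pair.

Gradients flow through a topologically sorted tape; broadcasting is undone
by summing gradient contributions over the broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = None

    # -- housekeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; tapes can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * _as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data ** 2))

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0.0, self.data, slope * self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0.0, 1.0, slope))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        # stable: exp of a non-positive argument only
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out

    def transpose(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = bw
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Select rows (axis 0) by integer index array; rows may repeat."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], parents=(self,))

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accumulate(acc)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- free functions --------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def segment_sum(values: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``values`` into ``num_segments`` buckets (axis 0)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    acc = np.zeros((num_segments,) + values.data.shape[1:], dtype=np.float64)
    np.add.at(acc, segment_ids, values.data)
    out = Tensor(acc, parents=(values,))

    def bw(g):
        if values.requires_grad:
            values._accumulate(g[segment_ids])

    out._backward = bw
    return out


def segment_softmax(logits: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a flat logit vector within each segment (in-neighborhood)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    # per-segment max as a detached shift: softmax is shift-invariant
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, logits.data)
    shifted = logits - Tensor(seg_max[segment_ids])
    ex = shifted.exp()
    denom = segment_sum(ex, segment_ids, num_segments)
    return ex / denom.gather_rows(segment_ids)


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax of a 2-D tensor (last axis)."""
    shift = x - Tensor(x.data.max(axis=-1, keepdims=True))
    ex = shift.exp()
    return ex / ex.sum(axis=-1, keepdims=True)


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE computed from logits: log(1+e^-|z|) + max(z,0) - z*y (stable)."""
    t = Tensor(np.asarray(targets, dtype=np.float64))
    z = logits
    # softplus(-|z|) via primitives would lose stability; use the identity
    # bce = max(z,0) - z*y + log(1+exp(-|z|)) with each piece differentiable.
    relu_z = z.relu()
    absz = z.relu() + (-z).relu()
    log_term = (Tensor(1.0) + (-absz).exp()).log()
    per = relu_z - z * t + log_term
    return per.mean()


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
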