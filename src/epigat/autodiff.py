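"""Reverse-mode automatic differentiation over numpy arrays.

This is the package's own lightweight tensor layer: a :class:`Tensor` wraps an
``ndarray`` and records the operations applied to it so that ``backward()`` can
propagate gradients through the full network and composite loss.  Only the
operations the masked-graph-attention model needs are implemented; every op's
gradient is exercised by finite-difference checks in the test suite.

Conventions
-----------
* Gradients accumulate into ``Tensor.grad`` (a plain ndarray).
* Broadcasting follows numpy; the backward pass sums gradients over the
  broadcast axes.
* Constants (labels, masks, thresholds) are passed as arrays or as Tensors
  with ``requires_grad=False``; no gradient is stored for them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "index_select", "scatter_add", "embedding_lookup", "masked_softmax", "log_softmax", "no_grad"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x
    return np.asarray(x, dtype=np.float64)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64)
        self.grad += g

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS to avoid recursion limits on deep graphs
        visit_state: dict[int, int] = {}
        while stack_:
            node = stack_[-1]
            nid = id(node)
            if visit_state.get(nid, 0) == 0:
                visit_state[nid] = 1
                for p in node._parents:
                    if p.requires_grad and visit_state.get(id(p), 0) == 0:
                        stack_.append(p)
            else:
                stack_.pop()
                if nid not in seen:
                    seen.add(nid)
                    topo.append(node)
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- matmul / shaping -----------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(src_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a, b):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(src_shape, dtype=np.float64)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        src_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accum(np.broadcast_to(g, src_shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, src_shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation, standard in transformer stacks
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
                self._accum(g * d)

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        out_data = np.where(pos, self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, slope))

        return Tensor._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward op."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tensors, backward)


def index_select(x: Tensor, idx: np.ndarray) -> Tensor:
    """Rows ``x[idx]`` along axis 0 (integer index array)."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data, dtype=np.float64)
            np.add.at(full, idx, g)
            x._accum(full)

    return Tensor._make(out_data, (x,), backward)


def scatter_add(src: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """``out[idx[e]] += src[e]`` over axis 0; output has ``n`` rows."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = np.zeros((n,) + src.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, idx, src.data)

    def backward(g):
        if src.requires_grad:
            src._accum(g[idx])

    return Tensor._make(out_data, (src,), backward)


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """``table[ids]`` where ids is an integer array of any shape."""
    ids = np.asarray(ids, dtype=np.intp)
    out_data = table.data[ids]

    def backward(g):
        if table.requires_grad:
            full = np.zeros_like(table.data, dtype=np.float64)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accum(full)

    return Tensor._make(out_data, (table,), backward)


def masked_softmax(scores: Tensor, key_mask: np.ndarray) -> Tensor:
    """Softmax over the last axis with invalid keys given exactly zero weight.

    ``key_mask`` broadcasts against ``scores``; True marks a valid key.  Rows
    with no valid key return all zeros (padded queries).
    """
    mask = np.broadcast_to(np.asarray(key_mask, dtype=bool), scores.data.shape)
    neg = np.where(mask, scores.data, -np.inf)
    mx = neg.max(axis=-1, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    ex = np.exp(neg - mx)
    ex = np.where(mask, ex, 0.0)
    denom = ex.sum(axis=-1, keepdims=True)
    safe = np.where(denom > 0, denom, 1.0)
    p = ex / safe

    def backward(g):
        if scores.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            scores._accum(p * (g - dot))

    return Tensor._make(p, (scores,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    mx = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - mx
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    sm = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), backward)
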