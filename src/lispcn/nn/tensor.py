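"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; :meth:`Tensor.backward` walks the graph in reverse
topological order accumulating gradients.  Only the operations needed by
the model family in this package are provided (elementwise arithmetic,
matmul, 2-D convolution via im2col, nearest-neighbour upsampling,
reductions and the usual activations).  Everything is plain numpy, so a
fixed seed gives bit-identical results on a single CPU.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, "Tensor"]


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor dispatch to the Tensor reflected operator
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[], None]] = None,
    ) -> None:
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[Tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep at many iterations
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self:
                    node._backward = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators --------------------------------------------------------

    def __add__(self, other: ArrayLike) -> "Tensor":
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return add(self, mul(other, -1.0))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return add(mul(self, -1.0), other)

    def __neg__(self) -> "Tensor":
        return mul(self, -1.0)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / float(np.asarray(other)))

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return mul(power(self, -1.0), other)

    def __pow__(self, exponent: float) -> "Tensor":
        return power(self, exponent)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return matmul(self, other)

    def reshape(self, *shape: int) -> "Tensor":
        return reshape(self, shape)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        return mean(self, axis=axis, keepdims=keepdims)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        return tsum(self, axis=axis, keepdims=keepdims)


def as_tensor(x: ArrayLike, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None:
        arr = arr.astype(dtype)
    return Tensor(arr)


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _binary(a: ArrayLike, b: ArrayLike):
    ta, tb = as_tensor(a), as_tensor(b)
    return ta, tb, (ta.requires_grad or tb.requires_grad)


def add(a: ArrayLike, b: ArrayLike) -> Tensor:
    ta, tb, rg = _binary(a, b)
    out = Tensor(ta.data + tb.data, rg, (ta, tb))

    def _bw(g_out) -> None:
        ta._accumulate(_unbroadcast(g_out, ta.shape))
        tb._accumulate(_unbroadcast(g_out, tb.shape))

    out._backward = _bw
    return out


def mul(a: ArrayLike, b: ArrayLike) -> Tensor:
    ta, tb, rg = _binary(a, b)
    out = Tensor(ta.data * tb.data, rg, (ta, tb))

    def _bw(g_out) -> None:
        ta._accumulate(_unbroadcast(g_out * tb.data, ta.shape))
        tb._accumulate(_unbroadcast(g_out * ta.data, tb.shape))

    out._backward = _bw
    return out


def power(a: ArrayLike, exponent: float) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(ta.data ** exponent, ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out * exponent * ta.data ** (exponent - 1.0))

    out._backward = _bw
    return out


def exp(a: ArrayLike) -> Tensor:
    ta = as_tensor(a)
    y = np.exp(ta.data)
    out = Tensor(y, ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out * y)

    out._backward = _bw
    return out


def log(a: ArrayLike) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(np.log(ta.data), ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out / ta.data)

    out._backward = _bw
    return out


def absolute(a: ArrayLike) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(np.abs(ta.data), ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out * np.sign(ta.data))

    out._backward = _bw
    return out


def clamp(a: ArrayLike, lo: float, hi: float) -> Tensor:
    """Clip values; gradient is zero where the input was clipped."""
    ta = as_tensor(a)
    out = Tensor(np.clip(ta.data, lo, hi), ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        inside = (ta.data >= lo) & (ta.data <= hi)
        ta._accumulate(g_out * inside)

    out._backward = _bw
    return out


def relu(a: ArrayLike) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(np.maximum(ta.data, 0.0), ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out * (ta.data > 0))

    out._backward = _bw
    return out


def leaky_relu(a: ArrayLike, slope: float = 0.2) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(np.where(ta.data > 0, ta.data, slope * ta.data),
                 ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out * np.where(ta.data > 0, 1.0, slope))

    out._backward = _bw
    return out


def tanh(a: ArrayLike) -> Tensor:
    ta = as_tensor(a)
    y = np.tanh(ta.data)
    out = Tensor(y, ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out * (1.0 - y ** 2))

    out._backward = _bw
    return out


def sigmoid(a: ArrayLike) -> Tensor:
    ta = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-ta.data))
    out = Tensor(s, ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out * s * (1.0 - s))

    out._backward = _bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    ta, tb, rg = _binary(a, b)
    out = Tensor(ta.data @ tb.data, rg, (ta, tb))

    def _bw(g_out) -> None:
        ta._accumulate(g_out @ tb.data.swapaxes(-1, -2))
        tb._accumulate(ta.data.swapaxes(-1, -2) @ g_out)

    out._backward = _bw
    return out


def reshape(a: Tensor, shape: Sequence[int]) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(ta.data.reshape(shape), ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        ta._accumulate(g_out.reshape(ta.shape))

    out._backward = _bw
    return out


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(ta.data.mean(axis=axis, keepdims=keepdims),
                 ta.requires_grad, (ta,))
    n = ta.data.size if axis is None else np.prod(
        [ta.shape[ax] for ax in np.atleast_1d(axis)])

    def _bw(g_out) -> None:
        g = g_out
        if not keepdims and axis is not None:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        ta._accumulate(np.broadcast_to(g, ta.shape) / n)

    out._backward = _bw
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    ta = as_tensor(a)
    out = Tensor(ta.data.sum(axis=axis, keepdims=keepdims),
                 ta.requires_grad, (ta,))

    def _bw(g_out) -> None:
        g = g_out
        if not keepdims and axis is not None:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        ta._accumulate(np.broadcast_to(g, ta.shape).astype(ta.dtype))

    out._backward = _bw
    return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis),
                 any(t.requires_grad for t in ts), tuple(ts))
    sizes = [t.shape[axis] for t in ts]

    def _bw(g_out) -> None:
        splits = np.cumsum(sizes)[:-1]
        for t, g in zip(ts, np.split(g_out, splits, axis=axis)):
            t._accumulate(g)

    out._backward = _bw
    return out


# -- convolution ----------------------------------------------------------

def _pad2d(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    n, c, h, w = x.shape
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=x.dtype)
    xp[:, :, ph:ph + h, pw:pw + w] = x
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1, padding: Union[int, Tuple[int, int]] = 0) -> Tensor:
    """NCHW convolution (cross-correlation), shift-and-accumulate form.

    The kernel is applied as kh*kw channel-mixing contractions on shifted
    views of the padded input — at the small channel counts used here
    this avoids the im2col memory blow-up entirely.
    """
    tx, tw = as_tensor(x), as_tensor(weight)
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    co, ci, kh, kw = tw.shape
    n, c, h, w_in = tx.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, "
                         f"weight expects {ci}")
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (w_in + 2 * pw - kw) // stride + 1
    xp = _pad2d(tx.data, ph, pw)
    y = np.zeros((n, co, ho, wo), dtype=tx.dtype)
    shifts = []
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            shifts.append((i, j, xs))
            y += np.einsum("oc,nchw->nohw", tw.data[:, :, i, j], xs)
    parents: list[Tensor] = [tx, tw]
    if bias is not None:
        tb = as_tensor(bias)
        y += tb.data.reshape(1, co, 1, 1)
        parents.append(tb)
    rg = any(p.requires_grad or p._parents for p in parents)
    out = Tensor(y, rg, tuple(parents))

    need_dw = tw.requires_grad
    need_dx = tx.requires_grad or bool(tx._parents)

    def _bw(g_out) -> None:
        g = g_out  # (n, co, ho, wo)
        dw = np.empty_like(tw.data) if need_dw else None
        dxp = np.zeros_like(xp) if need_dx else None
        for i, j, xs in shifts:
            if need_dw:
                dw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, xs)
            if need_dx:
                dxp[:, :, i:i + stride * ho:stride,
                    j:j + stride * wo:stride] += np.einsum(
                        "oc,nohw->nchw", tw.data[:, :, i, j], g)
        if need_dw:
            tw._accumulate(dw)
        if need_dx:
            tx._accumulate(dxp[:, :, ph:ph + h, pw:pw + w_in]
                           if (ph or pw) else dxp)
        if bias is not None and parents[2].requires_grad:
            parents[2]._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    tx = as_tensor(x)
    out = Tensor(tx.data.repeat(2, axis=2).repeat(2, axis=3),
                 tx.requires_grad, (tx,))

    def _bw(g_out) -> None:
        g = g_out
        n, c, h, w = g.shape
        tx._accumulate(g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

    out._backward = _bw
    return out
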