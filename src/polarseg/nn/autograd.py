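"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small dynamic-tape engine carrying exactly the operations
the segmentation network needs: broadcasting arithmetic, matmul, conv2d
(im2col), 2x2 pooling, nearest-neighbour upsampling, softmax, sigmoid,
indexing and concatenation.  Gradients are accumulated into ``.grad`` by
:meth:`Tensor.backward` in reverse topological order.

Everything is float64 and CPU-only; the engine favours clarity and
correctness (it is finite-difference-tested) over speed, which is adequate
at the toy scales this package trains at.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maximum", "minimum", "where_const"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basics ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go: closures capture large im2col buffers,
            # and non-leaf grads are never needed again
            if node._parents:
                node.grad = None
            node._backward = None
            node._parents = ()

    # -- broadcasting helpers ----------------------------------------------
    @staticmethod
    def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
        """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, dim in enumerate(shape):
            if dim == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    self._unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (self.data > 0)
        )
        return out

    def sigmoid(self):
        s = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 60))),
            np.exp(np.clip(self.data, -60, None))
            / (1.0 + np.exp(np.clip(self.data, -60, None))),
        )
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * s * (1 - s))
        return out

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            self._accumulate(gx)

        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))

        out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            if other.requires_grad:
                other._accumulate(np.matmul(np.swapaxes(self.data, -1, -2), g))

        out._backward = bw
        return out

    # -- spatial ops (NCHW) ---------------------------------------------------
    def avg_pool2(self):
        n, c, h, w = self.shape
        v = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        out = Tensor(v, parents=(self,))

        def bw(g):
            if self.requires_grad:
                gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
                self._accumulate(gx)

        out._backward = bw
        return out

    def max_pool2(self):
        n, c, h, w = self.shape
        blocks = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        v = blocks.max(axis=(3, 5))
        out = Tensor(v, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
            arg = flat.argmax(axis=-1)
            gx = np.zeros_like(flat)
            np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
            gx = gx.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accumulate(gx.reshape(self.data.shape))

        out._backward = bw
        return out

    def upsample2(self):
        v = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        out = Tensor(v, parents=(self,))

        def bw(g):
            if self.requires_grad:
                n, c, h2, w2 = g.shape
                gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                self._accumulate(gx)

        out._backward = bw
        return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; at ties the gradient goes to the first argument."""
    pick_a = a.data >= b.data
    out = Tensor(np.where(pick_a, a.data, b.data), parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * pick_a)
        if b.requires_grad:
            b._accumulate(g * ~pick_a)

    out._backward = bw
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise min; at ties the gradient goes to the first argument."""
    pick_a = a.data <= b.data
    out = Tensor(np.where(pick_a, a.data, b.data), parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * pick_a)
        if b.requires_grad:
            b._accumulate(g * ~pick_a)

    out._backward = bw
    return out


def where_const(cond: np.ndarray, x: Tensor, const: float) -> Tensor:
    """``where(cond, x, const)`` with a constant else-branch."""
    out = Tensor(np.where(cond, x.data, const), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * cond)
    return out


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


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input via im2col.

    ``w`` has shape (C_out, C_in, kh, kw); output spatial size is
    ``(H + 2p - kh)//s + 1``.
    """
    n, cin, h, wdt = x.shape
    cout, cin2, kh, kw = w.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin2}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (h + 2 * p - kh) // s + 1
    wo = (wdt + 2 * p - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (N, Cin, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, -1)
    y = cols @ wmat.T
    if b is not None:
        y = y + b.data
    y = y.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if w.requires_grad:
            w._accumulate((g2.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            gcols = (g2 @ wmat).reshape(n, ho, wo, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            x._accumulate(gxp[:, :, p : p + h, p : p + wdt] if p else gxp)

    out._backward = bw
    return out
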