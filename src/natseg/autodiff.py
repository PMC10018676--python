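"""A compact reverse-mode automatic differentiation engine on NumPy arrays.

The segmentation network, its losses, and the training loop are all built on
the :class:`Tensor` defined here.  The design is deliberately small: a tape of
parent links plus per-node backward closures, dense gradients, CPU only.
Only the operations the package needs are provided (elementwise arithmetic,
matmul, reductions, reshaping/indexing, 2-D convolution, bilinear resizing,
and the usual activation functions).

Gradients are accumulated into ``.grad`` (a NumPy array of the same shape as
``.data``) by calling :meth:`Tensor.backward` on a scalar result.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "bilinear_resize"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype if g.dtype.kind == "f" else np.float64)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep at high resolution)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype if self.data.dtype.kind == "f" else np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _coerce(self, other) -> "Tensor":
        """Wrap `other`, casting bare scalars to this tensor's float dtype so
        float64 constants never upcast a float32 graph."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if (arr.ndim == 0 and arr.dtype.kind == "f" and self.data.dtype.kind == "f"
                and arr.dtype != self.data.dtype):
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def _new(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad],
                      backward=backward if req else None)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            self.accumulate(_unbroadcast(g, self.shape))
            other.accumulate(_unbroadcast(g, other.shape))

        return self._new(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self.accumulate(-g)

        return self._new(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            self.accumulate(_unbroadcast(g * other.data, self.shape))
            other.accumulate(_unbroadcast(g * self.data, other.shape))

        return self._new(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            self.accumulate(_unbroadcast(g / other.data, self.shape))
            other.accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return self._new(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            self.accumulate(g * exponent * self.data ** (exponent - 1))

        return self._new(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b if a.ndim > 1 else np.outer(g, b)
                gb = (np.expand_dims(g, -1) * a).sum(axis=tuple(range(a.ndim - 1))) if a.ndim > 1 else g * a
                self.accumulate(_unbroadcast(ga, a.shape))
                other.accumulate(_unbroadcast(gb, b.shape))
                return
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self.accumulate(_unbroadcast(ga, a.shape))
            other.accumulate(_unbroadcast(gb, b.shape))

        return self._new(out_data, (self, other), backward)

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self.accumulate(g * out_data)

        return self._new(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self.accumulate(g / self.data)

        return self._new(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self.accumulate(g * 0.5 / out_data)

        return self._new(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self.accumulate(g * (1.0 - out_data ** 2))

        return self._new(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self.accumulate(g * out_data * (1.0 - out_data))

        return self._new(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self.accumulate(g * mask)

        return self._new(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation; smooth and cheap
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dt = (1.0 - t ** 2) * dinner
            self.accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return self._new(out_data, (self,), backward)

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def backward(g):
            self.accumulate(g * mask)

        return self._new(out_data, (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self.accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(g, self.shape).copy())

        return self._new(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self.accumulate(g.reshape(old))

        return self._new(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self.accumulate(g.transpose(inv))

        return self._new(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data, dtype=g.dtype)
            np.add.at(full, idx, g)
            self.accumulate(full)

        return self._new(out_data, (self,), backward)

    # -- composites -------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def item(self) -> float:
        return float(self.data)


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  parents=[t for t in tensors if t.requires_grad],
                  backward=backward if req else None)


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, dh: int, dw: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> windows (B, C, Ho, Wo, kh, kw) honoring stride/dilation."""
    eff_h = (kh - 1) * dh + 1
    eff_w = (kw - 1) * dw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eff_h, eff_w), axis=(2, 3))
    return win[:, :, ::sh, ::sw, ::dh, ::dw]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation: x (B, Cin, H, W) * w (Cout, Cin, kh, kw) -> (B, Cout, Ho, Wo)."""
    x = Tensor._wrap(x)
    w = Tensor._wrap(w)
    B, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d channel mismatch: input has {Cin}, kernel expects {Cin_w}")
    sh = sw = stride
    dh = dw = dilation
    p = padding
    eff_h = (kh - 1) * dh + 1
    eff_w = (kw - 1) * dw + 1
    if H + 2 * p < eff_h or W + 2 * p < eff_w:
        raise ValueError(f"conv2d: effective kernel ({eff_h}x{eff_w}) exceeds padded input "
                         f"({H + 2 * p}x{W + 2 * p})")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw)  # (B, Cin, Ho, Wo, kh, kw)
    out_data = np.tensordot(cols, w.data, axes=([1, 4, 5], [1, 2, 3]))  # (B, Ho, Wo, Cout)
    out_data = np.moveaxis(out_data, 3, 1)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    Ho, Wo = out_data.shape[2], out_data.shape[3]
    parents = [x, w] + ([b] if b is not None else [])

    def backward(g):
        # g: (B, Cout, Ho, Wo)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 2, 3]))  # (Cout, Cin, kh, kw)
            w.accumulate(gw)
        if x.requires_grad:
            gx_pad = np.zeros_like(xp, dtype=g.dtype)
            for a in range(kh):
                for c in range(kw):
                    # (B, Ho, Wo, Cin) contribution of tap (a, c)
                    gtap = np.tensordot(g, w.data[:, :, a, c], axes=([1], [0]))
                    gx_pad[:, :, a * dh: a * dh + sh * Ho: sh,
                           c * dw: c * dw + sw * Wo: sw] += np.moveaxis(gtap, 3, 1)
            gx = gx_pad[:, :, p:p + H, p:p + W] if p else gx_pad
            x.accumulate(gx)

    req = any(t.requires_grad for t in parents)
    return Tensor(out_data, requires_grad=req,
                  parents=[t for t in parents if t.requires_grad],
                  backward=backward if req else None)


def _resize_coords(n_in: int, n_out: int):
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = (src - i0).astype(np.float64)
    return i0, i1, t


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling of (B, C, H, W) to (B, C, out_h, out_w), half-pixel centers."""
    x = Tensor._wrap(x)
    B, C, H, W = x.shape
    i0, i1, ti = _resize_coords(H, out_h)
    j0, j1, tj = _resize_coords(W, out_w)
    ti_c = ti[None, None, :, None].astype(x.data.dtype if x.data.dtype.kind == "f" else np.float64)
    tj_c = tj[None, None, None, :].astype(ti_c.dtype)
    rows = x.data[:, :, i0, :] * (1 - ti_c) + x.data[:, :, i1, :] * ti_c
    out_data = rows[:, :, :, j0] * (1 - tj_c) + rows[:, :, :, j1] * tj_c

    def backward(g):
        g_rows = np.zeros((B, C, out_h, W), dtype=g.dtype)
        np.add.at(g_rows, np.s_[:, :, :, j0], g * (1 - tj_c))
        np.add.at(g_rows, np.s_[:, :, :, j1], g * tj_c)
        gx = np.zeros((B, C, H, W), dtype=g.dtype)
        np.add.at(gx, np.s_[:, :, i0, :], g_rows * (1 - ti_c))
        np.add.at(gx, np.s_[:, :, i1, :], g_rows * ti_c)
        x.accumulate(gx)

    return x._new(out_data, (x,), backward)
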