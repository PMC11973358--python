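"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the network architectures need:
broadcasted arithmetic, matmul, (grouped, strided) 2-D convolution,
max pooling, reductions, and pointwise nonlinearities.  Gradients are
accumulated on every node of the graph, so intermediate feature maps
can be inspected after ``backward`` (used by Grad-CAM).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
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
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self, grad=None) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
            )

        return Tensor._node(self.data / other.data, (self, other), bwd)

    def __pow__(self, exponent: float):
        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._node(self.data ** exponent, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor._node(self.data @ other.data, (self, other), bwd)

    # ----------------------------------------------------------- nonlinearity
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._node(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._node(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._node(np.log(self.data), (self,), bwd)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._node(self.data.reshape(shape), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._node(self.data[idx], (self,), bwd)

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims=False):
        axes = axis if isinstance(axis, tuple) else (axis,)
        out_data = self.data.max(axis=axes, keepdims=True)
        mask = self.data == out_data
        # split ties evenly so the gradient sums to 1 per reduced slice
        mask = mask / mask.sum(axis=axes, keepdims=True)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(g * mask)

        res = out_data if keepdims else out_data.squeeze(axis=axes)
        return Tensor._node(res, (self,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


# ---------------------------------------------------------------- convolution
def _conv_forward(xp, w, stride):
    """xp: padded (B,Cin,H,W); w: (Cout,Cin,kh,kw) -> (B,Cout,Ho,Wo)."""
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (B,Cin,Ho,Wo,kh,kw)
    return np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation with optional channel groups and bias."""
    B, cin, H, W = x.shape
    cout, cig, kh, kw = w.shape
    if cin % groups or cout % groups or cig != cin // groups:
        raise ValueError(
            f"incompatible channels/groups: in={cin} out={cout} groups={groups}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cog = cout // groups
    outs = []
    for g in range(groups):
        outs.append(
            _conv_forward(
                xp[:, g * cig:(g + 1) * cig],
                w.data[g * cog:(g + 1) * cog],
                stride,
            )
        )
    out_data = outs[0] if groups == 1 else np.concatenate(outs, axis=1)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def bwd(g_out):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for gi in range(groups):
            xs = xp[:, gi * cig:(gi + 1) * cig]
            go = g_out[:, gi * cog:(gi + 1) * cog]
            wg = w.data[gi * cog:(gi + 1) * cog]
            for i in range(kh):
                for j in range(kw):
                    xsl = xs[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
                    # (Cout_g, Cin_g) patch of the weight gradient
                    gw[gi * cog:(gi + 1) * cog, :, i, j] += np.tensordot(
                        go, xsl, axes=([0, 2, 3], [0, 2, 3])
                    )
                    gxp[:, gi * cig:(gi + 1) * cig,
                        i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += np.tensordot(
                        go, wg[:, :, i, j], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
        if padding:
            gx = gxp[:, :, padding:padding + H, padding:padding + W]
        else:
            gx = gxp
        x._accumulate(gx)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g_out.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out_data, parents, bwd)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    B, C, H, W = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    B_, C_, Ho, Wo, _, _ = win.shape
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    Hp = xp.shape[2]
    Wp = xp.shape[3]
    oh = np.arange(Ho)[:, None] * stride
    ow = np.arange(Wo)[None, :] * stride
    ri = oh[None, None] + arg // kernel   # row in padded input
    ci = ow[None, None] + arg % kernel

    def bwd(g):
        gxp = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
        bi = np.arange(B)[:, None, None, None]
        chi = np.arange(C)[None, :, None, None]
        np.add.at(gxp, (bi, chi, ri, ci), g)
        x._accumulate(gxp[:, :, padding:padding + H, padding:padding + W])

    return Tensor._node(out_data, (x,), bwd)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits (stable log-softmax)."""
    labels = np.asarray(labels)
    n, k = logits.shape
    shift = logits - logits.data.max(axis=1, keepdims=True)
    lse = shift.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    nll = (lse - (shift * onehot).sum(axis=1, keepdims=True)).sum() * (1.0 / n)
    return nll
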