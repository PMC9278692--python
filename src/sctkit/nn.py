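"""Minimal reverse-mode autodiff over NumPy arrays, sized for 2D conv nets.

Supports exactly the operations the translation model needs: broadcasted
arithmetic, abs/tanh/leaky-relu, reductions, slicing, zero-padding, strided
convolution (im2col via stride tricks) and zero-insertion upsampling for
transposed convolution.  Gradients flow through a recorded tape; call
``backward()`` on a scalar result.

This is intentionally a small engine, not a framework: float64 throughout,
single thread of control, no graph optimization.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "conv2d_transpose", "instance_norm",
           "avg_pool2d", "zero_insert2d", "pad2d", "swap01", "flip2d"]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse NumPy broadcasting: reduce ``grad`` back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        data = np.asarray(data)
        if data.dtype != np.float32:  # keep float32 throughout if given it
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- graph mechanics ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _sum_to_shape(np.asarray(grad, dtype=self.data.dtype),
                             self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        if not isinstance(other, Tensor):  # scalar constant: no promotion
            def bws(g):
                self._accum(g)

            return Tensor(self.data + other, parents=(self,), backward=bws)
        o = other

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if o.requires_grad:
                o._accum(g)

        return Tensor(self.data + o.data, parents=(self, o), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        if not isinstance(other, Tensor):
            return self + (-other)
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Tensor):
            def bws(g):
                self._accum(g * other)

            return Tensor(self.data * other, parents=(self,), backward=bws)
        o = other

        def bw(g):
            if self.requires_grad:
                self._accum(g * o.data)
            if o.requires_grad:
                o._accum(g * self.data)

        return Tensor(self.data * o.data, parents=(self, o), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor):
            return self * (1.0 / other)
        o = other

        def bw(g):
            if self.requires_grad:
                self._accum(g / o.data)
            if o.requires_grad:
                o._accum(-g * self.data / o.data**2)

        return Tensor(self.data / o.data, parents=(self, o), backward=bw)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g):
            self._accum(g * e * self.data ** (e - 1))

        return Tensor(self.data**e, parents=(self,), backward=bw)

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))

        return Tensor(np.abs(self.data), parents=(self,), backward=bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out**2))

        return Tensor(out, parents=(self,), backward=bw)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype,
                                                            copy=False)

        def bw(g):
            self._accum(g * factor)

        return Tensor(self.data * factor, parents=(self,), backward=bw)

    def relu(self):
        return self.leaky_relu(0.0)

    # -- reductions and shaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor(out, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accum(full)

        return Tensor(self.data[key], parents=(self,), backward=bw)

    def item(self) -> float:
        return float(self.data)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling of the trailing axes."""
    if k == 1:
        return x
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {(h, w)} not divisible by pool {k}")
    out = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def bw(g):
        up = np.repeat(np.repeat(g, k, axis=2), k, axis=3)
        x._accum(up * (1.0 / (k * k)))

    return Tensor(out, parents=(x,), backward=bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes (fused).

    y = gamma * (x - mu) / sqrt(var + eps) + beta with statistics over (H, W).
    """
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=x.data.dtype))
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3), keepdims=True))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3), keepdims=True))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=(2, 3), keepdims=True)
            m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out, parents=(x, gamma, beta), backward=bw)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Padded input (n,c,hp,wp) -> column matrix (n, c*kh*kw, ho*wo)."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols6 = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols6[:, :, i, j] = xp[:, :, i:i + stride * ho:stride,
                                   j:j + stride * wo:stride]
    return cols6.reshape(n, c * kh * kw, ho * wo)


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the trailing two axes symmetrically."""
    if pad == 0:
        return x
    widths = [(0, 0)] * (x.data.ndim - 2) + [(pad, pad), (pad, pad)]
    out = np.pad(x.data, widths)

    def bw(g):
        sl = tuple([slice(None)] * (x.data.ndim - 2)
                   + [slice(pad, -pad), slice(pad, -pad)])
        x._accum(g[sl])

    return Tensor(out, parents=(x,), backward=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2D cross-correlation: x (N,C,H,W), w (F,C,kh,kw) -> (N,F,Ho,Wo).

    im2col + matmul; the column matrix is kept for the backward pass.
    """
    xp = np.pad(x.data, [(0, 0), (0, 0), (pad, pad), (pad, pad)]) if pad else x.data
    n, c, hp, wp = xp.shape
    f, _, kh, kw = w.data.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride)
    wm = w.data.reshape(f, c * kh * kw)
    out = np.matmul(wm, cols).reshape(n, f, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def bw(g):
        g2 = g.reshape(n, f, ho * wo)
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(f, c, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride == 1:
                # dx is the full correlation of g with the flipped kernel
                gp = np.pad(np.asarray(g, dtype=xp.dtype),
                            [(0, 0), (0, 0), (kh - 1 - pad,) * 2,
                             (kw - 1 - pad,) * 2])
                gcols = _im2col(gp, kh, kw, 1)
                wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                dx = np.matmul(wflip.reshape(c, f * kh * kw), gcols)
                x._accum(dx.reshape(x.data.shape))
            else:
                dcols = np.matmul(wm.T, g2).reshape(n, c, kh, kw, ho, wo)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * ho:stride,
                            j:j + stride * wo:stride] += dcols[:, :, i, j]
                if pad:
                    gxp = gxp[:, :, pad:-pad, pad:-pad]
                x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=bw)


def zero_insert2d(x: Tensor, stride: int, extra: int = 0) -> Tensor:
    """Dilate the trailing axes by zero insertion (for transposed conv).

    Output spatial size is ``(n - 1) * stride + 1 + extra`` per axis, with
    ``extra`` trailing zeros implementing output padding.
    """
    n, c, h, wdt = x.data.shape
    out = np.zeros((n, c, (h - 1) * stride + 1 + extra,
                    (wdt - 1) * stride + 1 + extra), dtype=x.data.dtype)
    out[:, :, ::stride, ::stride][:, :, :h, :wdt] = x.data

    def bw(g):
        x._accum(g[:, :, ::stride, ::stride][:, :, :h, :wdt])

    return Tensor(out, parents=(x,), backward=bw)


def swap01(w: Tensor) -> Tensor:
    """Transpose the first two axes (channel swap for transposed conv)."""

    def bw(g):
        w._accum(np.swapaxes(g, 0, 1))

    return Tensor(np.swapaxes(w.data, 0, 1), parents=(w,), backward=bw)


def flip2d(w: Tensor) -> Tensor:
    """Flip the trailing two axes (kernel flip for transposed conv)."""

    def bw(g):
        w._accum(g[..., ::-1, ::-1])

    return Tensor(w.data[..., ::-1, ::-1], parents=(w,), backward=bw)


def conv2d_transpose(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, pad: int = 1, output_padding: int = 1) -> Tensor:
    """Transposed convolution with weight layout (C_in, C_out, kh, kw).

    Implemented as zero-insertion followed by a stride-1 convolution with the
    channel-swapped, spatially flipped kernel — the textbook equivalence.
    """
    kh = w.data.shape[2]
    dil = zero_insert2d(x, stride, extra=output_padding)
    return conv2d(dil, flip2d(swap01(w)), b, stride=1, pad=kh - 1 - pad)
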