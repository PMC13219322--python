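"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine providing exactly the operations the
frame-synthesis network needs: elementwise arithmetic, reductions, matmul,
im2col convolution, nearest-neighbour upsampling, softmax, and bilinear
backward warping with gradients to both the source and the flow. Every op
is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample2x", "warp", "matmul", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        # float64 ndarrays keep their precision (gradcheck); python scalars
        # and non-float inputs run in float32 so constants never promote the
        # whole graph
        if isinstance(data, (np.ndarray, np.generic)) and data.dtype == np.float64:
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data).astype(np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in out._parents)
        if out.requires_grad:
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)  # owns its buffer
        else:
            self.grad += g

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), back)

    def __pow__(self, p: float):
        def back(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), back)

    # -- elementwise non-linearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), back)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), back)

    def atanh(self, eps: float = 1e-3):
        """Inverse tanh of the input clipped to (-1+eps, 1-eps)."""
        clipped = np.clip(self.data, -1.0 + eps, 1.0 - eps)
        inside = (self.data > -1.0 + eps) & (self.data < 1.0 - eps)
        out_data = np.arctanh(clipped)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * inside / (1.0 - clipped**2))

        return Tensor._make(out_data, (self,), back)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor._make(np.where(mask, self.data, slope * self.data), (self,), back)

    def abs(self):
        sign = np.sign(self.data)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), back)

    # -- reductions and reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), back)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), back)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, back)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; batch dims must match or be absent on ``b``."""

    def back(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._make(np.matmul(a.data, b.data), (a, b), back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), back)


# ---------------------------------------------------------------------------
# convolution via im2col


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(b, c * kh * kw, ho * wo), (ho, wo, hp, wp)


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo):
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((b, c, hp, wp), dtype=dcols.dtype)
    dcols = dcols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout."""
    co, ci, kh, kw = weight.shape
    cols, (ho, wo, _, _) = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = np.matmul(wmat, cols).reshape(x.shape[0], co, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def back(g):
        gmat = g.reshape(g.shape[0], co, ho * wo)
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", gmat, cols)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)
            x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, pad, ho, wo))

    return Tensor._make(out, parents, back)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of an NCHW tensor."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def back(g):
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            gr = g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gr)

    return Tensor._make(out, (x,), back)


def avgpool2x(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    out = x.data.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def back(g):
        if x.requires_grad:
            gg = g[:, :, :, None, :, None] * 0.25
            x._accumulate(np.broadcast_to(gg, (b, c, h // 2, 2, w // 2, 2)).reshape(b, c, h, w))

    return Tensor._make(out, (x,), back)


def warp(source: Tensor, flow: Tensor) -> Tensor:
    """Backward bilinear warp: out(p) = source(p + flow(p)), border-clamped.

    ``source`` is (B, C, H, W); ``flow`` is (B, 2, H, W) with channel 0 the
    x (column) displacement and channel 1 the y (row) displacement.
    Gradients propagate to both the source and the flow; flow gradients
    vanish where sampling is clamped to the border.
    """
    b, c, h, w = source.shape
    if flow.shape != (b, 2, h, w):
        raise ValueError(f"flow shape {flow.shape} does not match source {source.shape}")
    yy, xx = np.meshgrid(np.arange(h, dtype=source.data.dtype), np.arange(w, dtype=source.data.dtype), indexing="ij")
    gx = xx[None] + flow.data[:, 0]
    gy = yy[None] + flow.data[:, 1]
    in_x = (gx > 0.0) & (gx < w - 1)
    in_y = (gy > 0.0) & (gy < h - 1)
    gx = np.clip(gx, 0.0, w - 1)
    gy = np.clip(gy, 0.0, h - 1)
    x0 = np.minimum(np.floor(gx), w - 2).astype(np.int64)
    y0 = np.minimum(np.floor(gy), h - 2).astype(np.int64)
    wx = (gx - x0.astype(gx.dtype))[:, None]  # (B,1,H,W)
    wy = (gy - y0.astype(gy.dtype))[:, None]
    bidx = np.arange(b)[:, None, None, None]
    cidx = np.arange(c)[None, :, None, None]
    i00 = source.data[bidx, cidx, y0[:, None], x0[:, None]]
    i01 = source.data[bidx, cidx, y0[:, None], x0[:, None] + 1]
    i10 = source.data[bidx, cidx, y0[:, None] + 1, x0[:, None]]
    i11 = source.data[bidx, cidx, y0[:, None] + 1, x0[:, None] + 1]
    out = (
        (1 - wy) * ((1 - wx) * i00 + wx * i01)
        + wy * ((1 - wx) * i10 + wx * i11)
    )

    def back(g):
        if source.requires_grad:
            gsrc = np.zeros((b * c, h * w), dtype=source.data.dtype)
            lin00 = np.broadcast_to(y0[:, None] * w + x0[:, None], (b, c, h, w)).reshape(b * c, h * w)
            w00 = ((1 - wy) * (1 - wx) * g).reshape(b * c, h * w)
            w01 = ((1 - wy) * wx * g).reshape(b * c, h * w)
            w10 = (wy * (1 - wx) * g).reshape(b * c, h * w)
            w11 = (wy * wx * g).reshape(b * c, h * w)
            rows = np.broadcast_to(np.arange(b * c)[:, None], lin00.shape)
            for lin, wv in ((lin00, w00), (lin00 + 1, w01), (lin00 + w, w10), (lin00 + w + 1, w11)):
                np.add.at(gsrc, (rows, lin), wv)
            source._accumulate(gsrc.reshape(source.shape))
        if flow.requires_grad:
            dix = (1 - wy) * (i01 - i00) + wy * (i11 - i10)
            diy = (1 - wx) * (i10 - i00) + wx * (i11 - i01)
            gfx = (g * dix).sum(axis=1) * in_x
            gfy = (g * diy).sum(axis=1) * in_y
            flow._accumulate(np.stack([gfx, gfy], axis=1))

    return Tensor._make(out, (source, flow), back)
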