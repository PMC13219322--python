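"""Network building blocks: convolutions, orientation-masked convolution
branches, linear layers, and global attention."""

from __future__ import annotations

import math

import numpy as np

from angiosynth.nn.autodiff import Tensor, concat, conv2d, matmul, softmax

DEFAULT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


class Module:
    """Base class with recursive parameter discovery."""

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name in sorted(vars(self)):
            obj = getattr(self, name)
            key = f"{prefix}{name}"
            if isinstance(obj, Tensor) and obj.requires_grad:
                out.append((key, obj))
            elif isinstance(obj, Module):
                out.extend(obj.named_parameters(f"{key}."))
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, weight_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        std = weight_scale * math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0, std, size=(c_out, c_in, k, k)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(1.0 / d_in)
        self.weight = Tensor(rng.normal(0, std, size=(d_in, d_out)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


def orientation_mask(angle_deg: float, k: int = 3) -> np.ndarray:
    """Binary k x k mask of the line through the kernel centre at an angle.

    0 degrees is horizontal, 90 vertical, angles measured counter-clockwise
    in image convention (rows increase downward).
    """
    c = k // 2
    a = math.radians(angle_deg)
    vx, vy = math.cos(a), -math.sin(a)  # line direction, y up
    mask = np.zeros((k, k), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dr, dc = i - c, j - c
            cross = dc * vy - dr * vx
            if abs(cross) < 0.45:
                mask[i, j] = 1.0
    return mask


class OrientedConv(Module):
    """3x3 convolution whose kernel support is masked to one orientation."""

    def __init__(self, c_in: int, c_out: int, angle_deg: float,
                 rng: np.random.Generator | None = None, init: str = "he"):
        rng = rng or np.random.default_rng(0)
        self.mask = Tensor(np.broadcast_to(orientation_mask(angle_deg), (c_out, c_in, 3, 3)).copy())
        n_active = int(self.mask.data[0, 0].sum())
        if init == "average":
            w = np.full((c_out, c_in, 3, 3), 1.0 / (n_active * c_in), dtype=np.float32)
        else:
            std = math.sqrt(2.0 / (c_in * n_active))
            w = rng.normal(0, std, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.angle_deg = float(angle_deg)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight * self.mask, self.bias, stride=1, pad=1)


class DirectionAwareBlock(Module):
    """Parallel orientation-masked convolution branches fused by a 1x1 mix.

    Masked-out kernel positions contribute exactly zero: the binary mask
    multiplies the weights in every forward pass, so the masked weights
    never see the input (their gradients are masked identically).
    """

    def __init__(self, c_in: int, c_out: int,
                 orientations=DEFAULT_ORIENTATIONS,
                 rng: np.random.Generator | None = None, init: str = "he"):
        if len(orientations) < 1:
            raise ValueError("need at least one orientation")
        rng = rng or np.random.default_rng(0)
        branch_c = max(c_out // len(orientations), 1)
        self.branches = [
            OrientedConv(c_in, branch_c, a, rng=rng, init=init) for a in orientations
        ]
        self.fuse = Conv2d(branch_c * len(orientations), c_out, k=1, rng=rng)
        self.orientations = tuple(float(a) for a in orientations)

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        return [b(x) for b in self.branches]

    def __call__(self, x: Tensor) -> Tensor:
        # all branches share one im2col: stack the masked kernels and run a
        # single convolution, which is equivalent to concatenating branches
        w_all = concat([b.weight * b.mask for b in self.branches], axis=0)
        b_all = concat([b.bias for b in self.branches], axis=0)
        stacked = conv2d(x, w_all, b_all, stride=1, pad=1)
        return self.fuse(stacked).leaky_relu()


def apply_dacb(
    features: np.ndarray,
    orientations=DEFAULT_ORIENTATIONS,
    block: DirectionAwareBlock | None = None,
    seed: int = 0,
    init: str = "he",
) -> np.ndarray:
    """Functional direction-aware convolution on a (C, H, W) feature map.

    Builds a seeded block when none is supplied. Output spatial shape equals
    the input spatial shape.
    """
    features = np.asarray(features, dtype=np.float32)
    if features.ndim != 3:
        raise ValueError("features must be (C, H, W)")
    c = features.shape[0]
    if block is None:
        block = DirectionAwareBlock(c, c, orientations, rng=np.random.default_rng(seed), init=init)
    out = block(Tensor(features[None]))
    return out.data[0]


def _sincos_position_encoding(h: int, w: int, c: int, dtype=np.float32) -> np.ndarray:
    """Fixed 2-D sinusoidal positional encoding, (C, H, W)."""
    pe = np.zeros((c, h, w), dtype=dtype)
    half = c // 2
    div = np.exp(np.arange(0, half, 2) * (-math.log(10000.0) / max(half, 1)))
    pos_h = np.arange(h)[:, None] * div[None]
    pos_w = np.arange(w)[:, None] * div[None]
    for k in range(div.size):
        pe[2 * k, :, :] = np.sin(pos_h[:, k])[:, None]
        pe[2 * k + 1, :, :] = np.cos(pos_h[:, k])[:, None]
        if half + 2 * k + 1 < c:
            pe[half + 2 * k, :, :] = np.sin(pos_w[:, k])[None, :]
            pe[half + 2 * k + 1, :, :] = np.cos(pos_w[:, k])[None, :]
    return pe


class GlobalAttention(Module):
    """Multi-head attention over flattened spatial tokens of NCHW maps.

    Used both intra-frame (query == key/value source) and inter-frame
    (query from the fused candidate, keys/values from several maps).
    A residual connection keeps early training stable.
    """

    def __init__(self, channels: int, n_heads: int = 4, rng: np.random.Generator | None = None,
                 key_dacb: DirectionAwareBlock | None = None):
        if channels % n_heads:
            raise ValueError("channels must be divisible by n_heads")
        rng = rng or np.random.default_rng(0)
        self.q = Linear(channels, channels, rng)
        self.k = Linear(channels, channels, rng)
        self.v = Linear(channels, channels, rng)
        self.out = Linear(channels, channels, rng)
        # damp the residual update at initialisation
        self.out.weight.data *= 0.1
        self.n_heads = n_heads
        self.channels = channels
        self.key_dacb = key_dacb

    def _tokens(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        pe = _sincos_position_encoding(h, w, c, dtype=x.data.dtype)
        return (x + Tensor(pe[None])).reshape(b, c, h * w).transpose((0, 2, 1))

    def __call__(self, query_map: Tensor, kv_maps: list[Tensor] | None = None) -> Tensor:
        b, c, h, w = query_map.shape
        q_tok = self._tokens(query_map)
        if kv_maps is None:
            kv_maps = [query_map]
        if self.key_dacb is not None:
            kv_maps = [self.key_dacb(m) for m in kv_maps]
        kv_tok = concat([self._tokens(m) for m in kv_maps], axis=1)
        nq, nk = q_tok.shape[1], kv_tok.shape[1]
        dh = c // self.n_heads

        def split_heads(t: Tensor, n: int) -> Tensor:
            return t.reshape(b, n, self.n_heads, dh).transpose((0, 2, 1, 3))

        q = split_heads(self.q(q_tok), nq)
        k = split_heads(self.k(kv_tok), nk)
        v = split_heads(self.v(kv_tok), nk)
        att = softmax(matmul(q, k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(dh)), axis=-1)
        mixed = matmul(att, v).transpose((0, 2, 1, 3)).reshape(b, nq, c)
        out_tok = self.out(mixed)
        return query_map + out_tok.transpose((0, 2, 1)).reshape(b, c, h, w)
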