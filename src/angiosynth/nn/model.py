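"""Flow-guided frame interpolation network.

Pipeline: a shared multi-scale encoder built from direction-aware
convolution blocks; coarse-to-fine bidirectional optical-flow estimation
with a refinement stack per scale; global attention at the bottleneck
(intra-frame on each encoding, inter-frame across the warped candidates);
backward warping and sigmoid-weighted fusion of both endpoint features; and
a multi-scale decoder producing a bounded residual on top of the
flow-warped photometric candidate.

The output activation is tanh applied to (residual + atanh(candidate)), so
an untrained network already reproduces the flow-warped blend of the two
endpoint frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from angiosynth.nn import autodiff as ad
from angiosynth.nn.autodiff import Tensor, concat, upsample2x
from angiosynth.nn.layers import (
    DEFAULT_ORIENTATIONS,
    Conv2d,
    DirectionAwareBlock,
    GlobalAttention,
    Module,
)


@dataclass
class ModelConfig:
    base_channels: int = 16
    n_scales: int = 3
    n_heads: int = 4
    orientations: tuple = DEFAULT_ORIENTATIONS
    use_attention: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    def channels_at(self, scale: int) -> int:
        """Channel width doubles at each coarser scale."""
        return self.base_channels * (2**scale)

    def to_dict(self) -> dict:
        return {
            "base_channels": self.base_channels,
            "n_scales": self.n_scales,
            "n_heads": self.n_heads,
            "orientations": list(self.orientations),
            "use_attention": self.use_attention,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["orientations"] = tuple(d.get("orientations", DEFAULT_ORIENTATIONS))
        return ModelConfig(**d)


@dataclass
class FlowField:
    """Per-pixel backward-sampling displacement map (dx, dy) in pixels."""

    flow: np.ndarray  # (H, W, 2)

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=np.float64)
        if self.flow.ndim != 3 or self.flow.shape[-1] != 2:
            raise ValueError("flow must be (H, W, 2)")
        if not np.all(np.isfinite(self.flow)):
            raise ValueError("flow must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.flow[..., 0], self.flow[..., 1])


@dataclass
class SynthesisRequest:
    frame0: np.ndarray
    frame1: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.frame0 = np.asarray(self.frame0, dtype=np.float64)
        self.frame1 = np.asarray(self.frame1, dtype=np.float64)
        if self.frame0.shape != self.frame1.shape:
            raise ValueError("frames must share a shape")
        if not -1.0 < self.t < 1.0:
            raise ValueError(
                "timestep must lie strictly inside (-1, 1); the endpoints are real frames"
            )


def backward_warp(source: np.ndarray, flow: FlowField | np.ndarray) -> np.ndarray:
    """Bilinear backward warp of an (H, W) or (H, W, C) array.

    out(p) = source sampled at p + flow(p); out-of-bounds samples clamp to
    the border; a zero flow is the exact identity.
    """
    if isinstance(flow, FlowField):
        flow = flow.flow
    flow = np.asarray(flow, dtype=np.float64)
    source = np.asarray(source, dtype=np.float64)
    squeeze = source.ndim == 2
    if squeeze:
        source = source[..., None]
    if source.shape[:2] != flow.shape[:2] or flow.shape[-1] != 2:
        raise ValueError("source and flow shapes do not agree")
    if np.all(flow == 0.0):
        out = source.copy()
        return out[..., 0] if squeeze else out
    src_t = Tensor(source.transpose(2, 0, 1)[None])
    flow_t = Tensor(flow.transpose(2, 0, 1)[None])
    out = ad.warp(src_t, flow_t).data[0].transpose(1, 2, 0)
    return out[..., 0] if squeeze else out


class FrameSynthesisModel(Module):
    """The full interpolation network. Operates on frames in [-1, 1]."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        S = cfg.n_scales

        # encoder (shared between the two input frames)
        self.stem = Conv2d(1, cfg.channels_at(0), rng=rng)
        self.enc_dacb = [
            DirectionAwareBlock(cfg.channels_at(s), cfg.channels_at(s), cfg.orientations, rng=rng)
            for s in range(S)
        ]
        self.enc_down = [
            Conv2d(cfg.channels_at(s - 1), cfg.channels_at(s), stride=2, rng=rng)
            for s in range(1, S)
        ]

        # flow estimation / refinement: one small stack per scale
        self.flow_conv1 = []
        self.flow_conv2 = []
        for s in range(S):
            c = cfg.channels_at(s)
            self.flow_conv1.append(Conv2d(2 * c + 5, c, rng=rng))
            head = Conv2d(c, 5, rng=rng)
            head.weight.data *= 0.0  # flows start at zero, fusion starts at 0.5
            self.flow_conv2.append(head)

        # bottleneck attention
        cb = cfg.channels_at(S - 1)
        if cfg.use_attention:
            heads = cfg.n_heads if cb % cfg.n_heads == 0 else 1
            key_dacb = DirectionAwareBlock(cb, cb, cfg.orientations, rng=rng)
            self.intra_attention = GlobalAttention(cb, heads, rng=rng, key_dacb=key_dacb)
            self.inter_attention = GlobalAttention(cb, heads, rng=rng)
        else:
            self.intra_attention = None
            self.inter_attention = None

        # decoder
        self.dec_reduce = [
            Conv2d(cfg.channels_at(s), cfg.channels_at(s - 1), rng=rng)
            for s in range(S - 1, 0, -1)
        ]
        self.dec_mix = [
            DirectionAwareBlock(2 * cfg.channels_at(s - 1), cfg.channels_at(s - 1),
                                cfg.orientations, rng=rng)
            for s in range(S - 1, 0, -1)
        ]
        self.head = Conv2d(cfg.channels_at(0), 1, rng=rng, weight_scale=0.1)

    # ------------------------------------------------------------------
    def encode(self, x: Tensor) -> list[Tensor]:
        """Feature pyramid, finest (scale 0) to coarsest."""
        feats = [self.enc_dacb[0](self.stem(x))]
        for s in range(1, self.config.n_scales):
            feats.append(self.enc_dacb[s](self.enc_down[s - 1](feats[-1]).leaky_relu()))
        return feats

    def _flow_pass(self, f0: list[Tensor], f1: list[Tensor], t: float):
        """Coarse-to-fine bidirectional flow + fused features per scale."""
        S = self.config.n_scales
        fused: dict[int, Tensor] = {}
        flow0 = flow1 = None
        logit = None
        for s in range(S - 1, -1, -1):
            a, b = f0[s], f1[s]
            if s == S - 1 and self.intra_attention is not None:
                a = self.intra_attention(a)
                b = self.intra_attention(b)
            bshape = (a.shape[0], 2, a.shape[2], a.shape[3])
            if flow0 is None:
                flow0 = Tensor(np.zeros(bshape, dtype=np.float32))
                flow1 = Tensor(np.zeros(bshape, dtype=np.float32))
            w0 = ad.warp(a, flow0)
            w1 = ad.warp(b, flow1)
            t_arr = np.asarray(t, dtype=np.float32).reshape(-1, 1, 1, 1)
            tmap = Tensor(
                np.broadcast_to(t_arr, (a.shape[0], 1, a.shape[2], a.shape[3])).copy()
            )
            inp = concat([w0, w1, flow0, flow1, tmap], axis=1)
            delta = self.flow_conv2[s](self.flow_conv1[s](inp).leaky_relu())
            flow0 = flow0 + _slice_channels(delta, 0, 2)
            flow1 = flow1 + _slice_channels(delta, 2, 4)
            logit = _slice_channels(delta, 4, 5)
            wa = ad.warp(a, flow0)
            wb = ad.warp(b, flow1)
            weight = logit.sigmoid()
            cand = weight * wa + (1.0 - weight) * wb
            if s == S - 1 and self.inter_attention is not None:
                cand = self.inter_attention(cand, [wa, wb, cand])
            fused[s] = cand
            if s > 0:
                flow0 = upsample2x(flow0) * 2.0
                flow1 = upsample2x(flow1) * 2.0
        return flow0, flow1, logit, fused

    def forward(self, x0: Tensor, x1: Tensor, t: float):
        """Full pass; returns (output, flow0, flow1) tensors."""
        b = x0.shape[0]
        feats = self.encode(concat([x0, x1], axis=0))  # shared weights: one pass
        f0 = [_slice_batch(f, 0, b) for f in feats]
        f1 = [_slice_batch(f, b, 2 * b) for f in feats]
        flow0, flow1, logit, fused = self._flow_pass(f0, f1, t)

        weight = logit.sigmoid()
        cand = weight * ad.warp(x0, flow0) + (1.0 - weight) * ad.warp(x1, flow1)

        S = self.config.n_scales
        d = fused[S - 1]
        for i, s in enumerate(range(S - 1, 0, -1)):
            d = upsample2x(self.dec_reduce[i](d).leaky_relu())
            d = self.dec_mix[i](concat([d, fused[s - 1]], axis=1))
        residual = self.head(d)
        out = (residual + cand.atanh()).tanh()
        return out, flow0, flow1

    # ------------------------------------------------------------------
    def _as_batch(self, frame: np.ndarray) -> Tensor:
        frame = np.asarray(frame, dtype=np.float32)
        if frame.ndim == 2:
            frame = frame[None, None]
        elif frame.ndim == 3:
            frame = frame[:, None]
        div = 2 ** (self.config.n_scales - 1)
        if frame.shape[-1] % div or frame.shape[-2] % div:
            raise ValueError(
                f"frame size must be divisible by {div} for {self.config.n_scales} scales"
            )
        return Tensor(frame)

    def synthesize(self, frame0: np.ndarray, frame1: np.ndarray, t: float) -> np.ndarray:
        """Numpy convenience wrapper for a single frame pair."""
        req = SynthesisRequest(frame0, frame1, t)
        out, _, _ = self.forward(self._as_batch(req.frame0), self._as_batch(req.frame1), req.t)
        return out.data[0, 0].astype(np.float64)

    def estimate_bidirectional_flow(
        self, frame0: np.ndarray, frame1: np.ndarray, t: float = 0.0
    ) -> tuple[FlowField, FlowField]:
        """Full-resolution backward flows from the target time into each frame."""
        x0 = self._as_batch(np.asarray(frame0, dtype=np.float32))
        x1 = self._as_batch(np.asarray(frame1, dtype=np.float32))
        f0 = self.encode(x0)
        f1 = self.encode(x1)
        flow0, flow1, _, _ = self._flow_pass(f0, f1, t)
        return (
            FlowField(flow0.data[0].transpose(1, 2, 0)),
            FlowField(flow1.data[0].transpose(1, 2, 0)),
        )


def _slice_batch(x: Tensor, a: int, b: int) -> Tensor:
    data = x.data[a:b]

    def back(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[a:b] = g
            x._accumulate(full)

    return Tensor._make(data, (x,), back)


def _slice_channels(x: Tensor, a: int, b: int) -> Tensor:
    data = x.data[:, a:b]

    def back(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, a:b] = g
            x._accumulate(full)

    return Tensor._make(data, (x,), back)


def synthesize_intermediate(req: SynthesisRequest, model: FrameSynthesisModel) -> np.ndarray:
    """Synthesize the frame at interior timestep ``req.t``; output in [-1, 1]."""
    return model.synthesize(req.frame0, req.frame1, req.t)
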