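"""Training protocol: composite pixel/structural/perceptual loss with a
two-phase weight schedule, cosine-annealed AdamW, and the training loop."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from angiosynth.nn import autodiff as ad
from angiosynth.nn.autodiff import Tensor
from angiosynth.nn.layers import Conv2d, Module
from angiosynth.nn.model import FrameSynthesisModel
from angiosynth.nn.optim import AdamW
from angiosynth.preprocess import assign_timesteps
from angiosynth.types import FrameSequence

PHASE1_WEIGHTS = (1.0, 1.0, 0.0, 0.0)
PHASE2_WEIGHTS = (0.5, 0.7, 40.0, 40.0)


@dataclass(frozen=True)
class LossWeights:
    alpha: float  # pixel L1
    beta: float  # structural (1 - SSIM)
    gamma: float  # perceptual L1
    delta: float  # perceptual MSE

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.delta) < 0:
            raise ValueError("loss weights must be non-negative")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta, self.gamma, self.delta)


@dataclass
class TrainConfig:
    lr_init: float = 1e-4
    lr_min: float = 1e-18
    cosine_period: int = 50
    total_epochs: int = 1000
    phase1_epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    n_generated: int = 6  # N of the acquisition protocol trained for
    batches_per_epoch: int | None = None  # None: one pass over all blocks
    anneal: str = "restart"  # "restart" (warm restarts) or "single"
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.lr_min >= self.lr_init:
            raise ValueError("lr_min must be smaller than lr_init")
        if self.phase1_epochs > self.total_epochs:
            raise ValueError("phase1_epochs must not exceed total_epochs")
        if self.anneal not in ("restart", "single"):
            raise ValueError("anneal must be 'restart' or 'single'")


def default_batch_size(n_generated: int) -> int:
    """Batch 8 when generating up to 6 frames, 4 for 7-8."""
    return 8 if n_generated <= 6 else 4


def loss_weights_at_epoch(epoch: int, cfg: TrainConfig) -> LossWeights:
    """(1, 1, 0, 0) during the first phase, (0.5, 0.7, 40, 40) afterwards."""
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError("epoch out of range")
    w = PHASE1_WEIGHTS if epoch < cfg.phase1_epochs else PHASE2_WEIGHTS
    return LossWeights(*w)


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate.

    Default reading: warm restarts with the configured period, i.e.
    lr = lr_min + (lr_init - lr_min) (1 + cos(pi (e mod P) / P)) / 2.
    The alternative single-anneal reading spans total_epochs.
    """
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError("epoch out of range")
    if cfg.anneal == "restart":
        frac = (epoch % cfg.cosine_period) / cfg.cosine_period
    else:
        frac = epoch / cfg.total_epochs
    return cfg.lr_min + 0.5 * (cfg.lr_init - cfg.lr_min) * (1.0 + math.cos(math.pi * frac))


# ---------------------------------------------------------------------------
# composite loss


class PerceptualExtractor(Module):
    """Fixed (non-trainable) multi-stage convolutional feature extractor.

    Offline substitute for a pretrained backbone: weights are seeded and
    frozen so the perceptual terms are well-defined and reproducible without
    any weight download. Features are taken after each of the three stages.
    """

    def __init__(self, seed: int = 0, channels=(8, 16, 32)):
        rng = np.random.default_rng(seed)
        c_in = 1
        self.stages = []
        for c_out in channels:
            conv = Conv2d(c_in, c_out, stride=2, rng=rng)
            conv.weight.requires_grad = False
            conv.bias.requires_grad = False
            self.stages.append(conv)
            c_in = c_out

    def features(self, x: Tensor) -> list[Tensor]:
        out = []
        for stage in self.stages:
            x = stage(x).leaky_relu()
            out.append(x)
        return out


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - size // 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return (k / k.sum()).astype(np.float32)


_SSIM_WIN = Tensor(_gaussian_kernel()[None, None])
_SSIM_C1 = 0.01**2
_SSIM_C2 = 0.03**2


def _ssim_mean(x: Tensor, y: Tensor) -> Tensor:
    """Differentiable Gaussian-window SSIM (11x11, sigma 1.5, range 1)."""
    pad = _SSIM_WIN.shape[-1] // 2

    def filt(t: Tensor) -> Tensor:
        return ad.conv2d(t, _SSIM_WIN, None, stride=1, pad=pad)

    mu_x, mu_y = filt(x), filt(y)
    var_x = filt(x * x) - mu_x * mu_x
    var_y = filt(y * y) - mu_y * mu_y
    cov = filt(x * y) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + _SSIM_C1) * (2.0 * cov + _SSIM_C2)
    den = (mu_x * mu_x + mu_y * mu_y + _SSIM_C1) * (var_x + var_y + _SSIM_C2)
    return (num / den).mean()


def composite_loss_tensor(
    pred: Tensor,
    target: Tensor,
    weights: LossWeights,
    feat_extractor: PerceptualExtractor | None = None,
) -> Tensor:
    """Differentiable composite loss on (B, 1, H, W) tensors in [-1, 1]."""
    if pred.shape != target.shape:
        raise ValueError("pred and target must share a shape")
    loss = Tensor(np.float32(0.0))
    if weights.alpha > 0:
        loss = loss + weights.alpha * (pred - target).abs().mean()
    # shift to [0, 1]: SSIM constants and feature statistics assume a
    # non-negative dynamic range
    up = (pred + 1.0) * 0.5
    ut = (target + 1.0) * 0.5
    if weights.beta > 0:
        loss = loss + weights.beta * (1.0 - _ssim_mean(up, ut))
    if weights.gamma > 0 or weights.delta > 0:
        if feat_extractor is None:
            feat_extractor = PerceptualExtractor(seed=0)
        fp = feat_extractor.features(up)
        ft = feat_extractor.features(ut)
        for a, b in zip(fp, ft):
            diff = a - b
            if weights.gamma > 0:
                loss = loss + weights.gamma * diff.abs().mean()
            if weights.delta > 0:
                loss = loss + weights.delta * (diff * diff).mean()
    return loss


def composite_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: LossWeights,
    feat_extractor: PerceptualExtractor | None = None,
) -> float:
    """Scalar composite loss on numpy frames in [-1, 1] (any 2D/3D shape)."""
    pred = np.asarray(pred, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if pred.ndim == 2:
        pred, target = pred[None], target[None]
    val = composite_loss_tensor(
        Tensor(pred[:, None]), Tensor(target[:, None]), weights, feat_extractor
    )
    return float(val.data)


# ---------------------------------------------------------------------------
# training loop


def _training_samples(frames: np.ndarray, gap: int) -> list[tuple[int, int, int]]:
    """All (first, target, last) index triples for blocks of span ``gap``."""
    L = frames.shape[0]
    triples = []
    for a in range(0, L - gap, gap):
        b = min(a + gap, L - 1)
        for i in range(a + 1, b):
            triples.append((a, i, b))
    return triples


def train_model(
    model: FrameSynthesisModel,
    dataset: list[FrameSequence] | list[np.ndarray],
    cfg: TrainConfig,
    feat_extractor: PerceptualExtractor | None = None,
    verbose: bool = False,
) -> tuple[FrameSynthesisModel, list[dict]]:
    """Run the optimization schedule; returns the model and loss history.

    ``dataset`` holds preprocessed sequences with frames in [-1, 1]. Every
    sequence must have at least 3 frames (an interior frame to supervise).
    """
    stacks = []
    for seq in dataset:
        frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
        if frames.shape[0] < 3:
            raise ValueError("every training sequence needs >= 3 frames")
        stacks.append(frames.astype(np.float32))
    if not stacks:
        raise ValueError("dataset is empty")

    if feat_extractor is None:
        feat_extractor = PerceptualExtractor(seed=0)
    rng = np.random.default_rng(cfg.seed)
    gap = cfg.n_generated + 1
    pool = []  # (sequence index, first, target, last)
    for si, frames in enumerate(stacks):
        g = min(gap, frames.shape[0] - 1)
        for a, i, b in _training_samples(frames, g):
            pool.append((si, a, i, b))
    if not pool:
        raise ValueError("no interior frames to supervise at this block span")

    opt = AdamW(model.parameters(), lr=cfg.lr_init, weight_decay=cfg.weight_decay)
    history: list[dict] = []
    n_batches = cfg.batches_per_epoch or max(len(pool) // cfg.batch_size, 1)

    for epoch in range(cfg.total_epochs):
        weights = loss_weights_at_epoch(epoch, cfg)
        opt.lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(len(pool))
        losses = []
        for bi in range(n_batches):
            take = [pool[order[(bi * cfg.batch_size + k) % len(pool)]]
                    for k in range(cfg.batch_size)]
            # group by timestep so one forward pass serves the whole batch
            f0 = np.stack([stacks[si][a] for si, a, _, _ in take])
            f1 = np.stack([stacks[si][b] for si, _, _, b in take])
            tg = np.stack([stacks[si][i] for si, _, i, _ in take])
            ts = np.array(
                [assign_timesteps(b - a + 1)[i - a] for _, a, i, b in take],
                dtype=np.float32,
            )
            out, _, _ = model.forward(model._as_batch(f0), model._as_batch(f1), ts)
            batch_loss = composite_loss_tensor(
                out, Tensor(tg[:, None]), weights, feat_extractor
            )
            model.zero_grad()
            batch_loss.backward()
            opt.step()
            losses.append(float(batch_loss.data))
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "loss": float(np.mean(losses)),
                "weights": weights.as_tuple(),
            }
        )
        if verbose:
            print(f"epoch {epoch}: loss {history[-1]['loss']:.5f} lr {opt.lr:.2e}")
    return model, history
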