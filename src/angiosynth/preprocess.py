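"""Standardisation pipeline: pad-to-square, resize, crop, normalisation,
and timestep assignment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as _tf

from angiosynth.types import FrameSequence


@dataclass
class PreprocessConfig:
    train_size: int = 128
    finetune_crop: int = 512
    pad_value: float | None = None  # None: use the image minimum

    def __post_init__(self) -> None:
        if self.train_size <= 0 or self.finetune_crop <= 0:
            raise ValueError("sizes must be positive")
        if self.train_size > self.finetune_crop:
            raise ValueError("train_size must not exceed finetune_crop")


def pad_and_resize(image: np.ndarray, target: int, pad_value: float | None = None) -> np.ndarray:
    """Pad an image symmetrically to a square, then resize to target x target.

    Aspect ratio of the content is preserved (padding, not anisotropic
    scaling). The pad value defaults to the image minimum so that padding
    never masquerades as vessel signal on the light-background convention.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    h, w = image.shape
    side = max(h, w)
    if pad_value is None:
        pad_value = float(image.min())
    if h != w:
        pr, pc = side - h, side - w
        image = np.pad(
            image,
            ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)),
            constant_values=pad_value,
        )
    if side == target:
        return image
    return _tf.resize(
        image, (target, target), order=1, mode="edge",
        anti_aliasing=side > target, preserve_range=True,
    )


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [-1, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains NaN or Inf")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return 2.0 * (image - lo) / (hi - lo) - 1.0


def normalize_sequence(frames: np.ndarray, per_frame: bool = True) -> np.ndarray:
    """Min-max normalise a (T, H, W) stack to [-1, 1].

    per_frame=True normalises each frame independently (the default
    reading); per_frame=False uses one global min/max for the whole
    sequence, which preserves relative time-intensity amplitudes.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if per_frame:
        return np.stack([minmax_normalize(f) for f in frames])
    if not np.all(np.isfinite(frames)):
        raise ValueError("frames contain NaN or Inf")
    lo, hi = frames.min(), frames.max()
    if hi == lo:
        return np.zeros_like(frames)
    return 2.0 * (frames - lo) / (hi - lo) - 1.0


def assign_timesteps(n_frames: int) -> np.ndarray:
    """Uniform timesteps in [-1, 1]: -1 for the first frame, 1 for the last.

    t_i = (2i - (n-1)) / (n-1); exactly antisymmetric (t_i == -t_{n-1-i}).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    i = np.arange(n_frames, dtype=np.float64)
    return (2.0 * i - (n_frames - 1)) / (n_frames - 1)


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    h, w = image.shape
    if size > h or size > w:
        raise ValueError("crop size exceeds image")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return image[r0 : r0 + size, c0 : c0 + size]


def random_crop(image: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    h, w = image.shape
    if size > h or size > w:
        raise ValueError("crop size exceeds image")
    r0 = int(rng.integers(0, h - size + 1))
    c0 = int(rng.integers(0, w - size + 1))
    return image[r0 : r0 + size, c0 : c0 + size]


def preprocess_sequence(
    seq: FrameSequence,
    target: int = 128,
    per_frame: bool = True,
    pad_value: float | None = None,
) -> FrameSequence:
    """Pad+resize every frame and normalise the stack to [-1, 1]."""
    resized = np.stack([pad_and_resize(f, target, pad_value) for f in seq.frames])
    out = seq.copy()
    out.frames = normalize_sequence(resized, per_frame=per_frame)
    return out
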