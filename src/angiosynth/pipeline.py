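"""Sparse acquisition pipeline: subsample 1 real frame per (N+1)-frame
block, synthesize the interior frames, reassemble, and account for dose."""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

import numpy as np

from angiosynth.nn.model import FrameSynthesisModel
from angiosynth.preprocess import assign_timesteps
from angiosynth.types import FrameSequence

#: interpolator signature: (frame0, frame1, timestep in (-1, 1)) -> frame
Interpolator = Callable[[np.ndarray, np.ndarray, float], np.ndarray]

MAX_EVALUATED_N = 8


@dataclass(frozen=True)
class AcquisitionProtocol:
    """N generated frames per acquired real frame; block length N+1."""

    n_generated: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_generated <= MAX_EVALUATED_N:
            raise ValueError(f"N must be in [0, {MAX_EVALUATED_N}]")

    @property
    def block(self) -> int:
        return self.n_generated + 1

    @property
    def dose_fraction(self) -> Fraction:
        return Fraction(1, self.block)

    @property
    def percent_reduction(self) -> float:
        return 100.0 * self.n_generated / self.block


def dose_fraction(n_generated: int) -> float:
    """Dose fraction 1/(N+1) under the sparse protocol (dose is
    proportional to the number of acquired frames)."""
    if n_generated < 0:
        raise ValueError("N must be >= 0")
    return 1.0 / (n_generated + 1)


def percent_reduction(n_generated: int) -> float:
    """Companion value 100 * N / (N+1)."""
    if n_generated < 0:
        raise ValueError("N must be >= 0")
    return 100.0 * n_generated / (n_generated + 1)


def subsample(seq: FrameSequence, n_generated: int) -> tuple[np.ndarray, list[int]]:
    """Keep one real frame per (N+1)-frame block.

    Kept indices are {0, N+1, 2(N+1), ...} plus the final index: a trailing
    partial block always retains its real endpoint so reconstruction can
    interpolate every interior frame between two real frames.
    """
    L = seq.n_frames
    if n_generated < 0:
        raise ValueError("N must be >= 0")
    if L < n_generated + 2:
        raise ValueError(
            f"sequence of {L} frames is too short for N={n_generated}: "
            "nothing to synthesize"
        )
    indices = list(range(0, L, n_generated + 1))
    if indices[-1] != L - 1:
        indices.append(L - 1)
    return seq.frames[indices].copy(), indices


def linear_blend_interpolator(f0: np.ndarray, f1: np.ndarray, t: float) -> np.ndarray:
    """Oracle interpolator: time-weighted average; t=0 is the exact mean."""
    w = (t + 1.0) / 2.0
    return (1.0 - w) * f0 + w * f1


def repeat_first_interpolator(f0: np.ndarray, f1: np.ndarray, t: float) -> np.ndarray:
    """Frame-repeat baseline: hold the preceding real frame."""
    return f0.copy()


def model_interpolator(model: FrameSynthesisModel) -> Interpolator:
    def interp(f0: np.ndarray, f1: np.ndarray, t: float) -> np.ndarray:
        return model.synthesize(f0, f1, t)

    return interp


def reconstruct_sequence(
    real_frames: np.ndarray,
    real_indices: list[int],
    length: int,
    interpolator: Interpolator,
) -> np.ndarray:
    """Reassemble a full-length sequence from sparse real frames.

    Real frames are copied bit-exact at their indices. Each interior frame i
    of a block (a, b) is synthesized at timestep t = -1 + 2 (i - a)/(b - a),
    matching the uniform timestep grid. Adjacent real frames (gap 1) are a
    valid block contributing nothing.
    """
    real_indices = list(real_indices)
    if sorted(real_indices) != real_indices or len(set(real_indices)) != len(real_indices):
        raise ValueError("real_indices must be sorted and unique")
    if real_indices[0] != 0 or real_indices[-1] != length - 1:
        raise ValueError("real_indices must include 0 and length-1")
    if len(real_frames) != len(real_indices):
        raise ValueError("one real frame per real index required")

    out = np.empty((length,) + tuple(np.shape(real_frames[0])), dtype=np.asarray(real_frames[0]).dtype)
    for frame, idx in zip(real_frames, real_indices):
        out[idx] = frame
    for (a, fa), (b, fb) in zip(
        zip(real_indices[:-1], real_frames[:-1]),
        zip(real_indices[1:], real_frames[1:]),
    ):
        if b - a < 2:
            continue
        ts = assign_timesteps(b - a + 1)
        for i in range(a + 1, b):
            out[i] = interpolator(fa, fb, float(ts[i - a]))
    return out


def dose_report(n_generated: int, total_frames: int, acquired_frames: int) -> dict:
    """JSON-ready accounting of the acquisition protocol."""
    p = AcquisitionProtocol(n_generated)
    return {
        "N": n_generated,
        "acquired": acquired_frames,
        "total": total_frames,
        "dose_fraction": float(p.dose_fraction),
        "percent_reduction": p.percent_reduction,
    }
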