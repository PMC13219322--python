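"""Core container types shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODES = ("2d", "3d")


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames : (T, H, W) float array
        Intensity frames, light background / dark vessels.
    frame_times : (T,) array
        Monotone acquisition times (frame index units).
    mode : {"2d", "3d"}
        Fixed-view planar mode or rotational mode.
    angles_deg : (T,) array
        Per-frame C-arm angle; all zero in 2d mode, spanning 180 in 3d.
    pixel_spacing : float
        Physical pixel size in mm/px.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    mode: str = "2d"
    angles_deg: np.ndarray | None = None
    pixel_spacing: float = 0.3

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        t, h, w = self.frames.shape
        if t < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if h < 16 or w < 16:
            raise ValueError("frames must be at least 16x16")
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.frame_times.shape != (t,):
            raise ValueError("frame_times length must match frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.angles_deg is None:
            self.angles_deg = np.zeros(t)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.angles_deg.shape != (t,):
            raise ValueError("angles_deg length must match frame count")
        if self.mode == "3d" and np.any(np.diff(self.angles_deg) < 0):
            raise ValueError("angles must be monotone in 3d mode")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def copy(self) -> "FrameSequence":
        return FrameSequence(
            frames=self.frames.copy(),
            frame_times=self.frame_times.copy(),
            mode=self.mode,
            angles_deg=self.angles_deg.copy(),
            pixel_spacing=self.pixel_spacing,
        )


@dataclass
class GroundTruth:
    """Simulator-side truth accompanying a rendered sequence.

    vessel_mask : (T, H, W) bool array of vessel pixels per frame.
    tic_points : list of ((row, col), (T,) series) pairs giving the
        noise-free time-intensity series at probe pixels.
    tip_xy : (T, 2) float array of guidewire tip (row, col) or None.
    """

    vessel_mask: np.ndarray
    tic_points: list = field(default_factory=list)
    tip_xy: np.ndarray | None = None

    def validate_against(self, seq: FrameSequence) -> None:
        if self.vessel_mask.shape != seq.frames.shape:
            raise ValueError("vessel_mask shape must match frames")
        if self.tip_xy is not None:
            t, h, w = seq.frames.shape
            if self.tip_xy.shape != (t, 2):
                raise ValueError("tip_xy must be (T, 2)")
            if (
                np.any(self.tip_xy < 0)
                or np.any(self.tip_xy[:, 0] > h - 1)
                or np.any(self.tip_xy[:, 1] > w - 1)
            ):
                raise ValueError("tip coordinates out of image bounds")
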