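"""Sequence containers on disk: multi-frame TIFF + JSON sidecar.

Frames are stored as 16-bit grayscale TIFF pages (intensities in [0, 1]
scaled to the uint16 range). Ground truth is stored as JSON plus per-frame
PNG masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from angiosynth.types import FrameSequence, GroundTruth

_U16 = np.float64(65535.0)


def write_sequence(seq: FrameSequence, directory: str | Path, stem: str = "sequence") -> Path:
    """Write frames to ``<dir>/<stem>.tif`` and metadata to ``<stem>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif_path = directory / f"{stem}.tif"
    data = np.clip(seq.frames, 0.0, 1.0)
    tifffile.imwrite(tif_path, (data * _U16 + 0.5).astype(np.uint16))
    sidecar = {
        "mode": seq.mode,
        "frame_times": seq.frame_times.tolist(),
        "angles_deg": seq.angles_deg.tolist(),
        "pixel_spacing": seq.pixel_spacing,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return tif_path


def read_sequence(directory: str | Path, stem: str = "sequence") -> FrameSequence:
    directory = Path(directory)
    frames = tifffile.imread(directory / f"{stem}.tif").astype(np.float64) / _U16
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads((directory / f"{stem}.json").read_text())
    return FrameSequence(
        frames=frames,
        frame_times=np.asarray(meta["frame_times"]),
        mode=meta["mode"],
        angles_deg=np.asarray(meta["angles_deg"]),
        pixel_spacing=float(meta["pixel_spacing"]),
    )


def write_ground_truth(gt: GroundTruth, directory: str | Path, stem: str = "truth") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "tic_points": [
            {"pixel": [int(p[0]), int(p[1])], "series": np.asarray(s).tolist()}
            for p, s in gt.tic_points
        ],
        "tip_xy": gt.tip_xy.tolist() if gt.tip_xy is not None else None,
    }
    path = directory / f"{stem}.json"
    path.write_text(json.dumps(payload, indent=1))
    mask_dir = directory / f"{stem}_masks"
    mask_dir.mkdir(exist_ok=True)
    for t in range(gt.vessel_mask.shape[0]):
        img = Image.fromarray((gt.vessel_mask[t] * 255).astype(np.uint8))
        img.save(mask_dir / f"mask_{t:04d}.png")
    return path


def read_ground_truth(directory: str | Path, stem: str = "truth") -> GroundTruth:
    directory = Path(directory)
    payload = json.loads((directory / f"{stem}.json").read_text())
    mask_dir = directory / f"{stem}_masks"
    mask_files = sorted(mask_dir.glob("mask_*.png"))
    masks = np.stack([np.asarray(Image.open(f)) > 127 for f in mask_files])
    return GroundTruth(
        vessel_mask=masks,
        tic_points=[
            ((d["pixel"][0], d["pixel"][1]), np.asarray(d["series"]))
            for d in payload["tic_points"]
        ],
        tip_xy=None if payload["tip_xy"] is None else np.asarray(payload["tip_xy"]),
    )
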