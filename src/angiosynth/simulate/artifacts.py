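"""Seeded artifact injection: motion blends and subtraction ghosts.

Affected pixels are the sub-level set of a smooth random field, so the
affected-pixel fraction is exactly monotone in severity for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as _ndi

from angiosynth.types import FrameSequence

ARTIFACT_KINDS = ("motion", "subtraction_ghost")


def inject_artifacts(
    seq: FrameSequence,
    severity: float,
    kind: str = "subtraction_ghost",
    frames_affected=None,
    seed: int = 0,
) -> FrameSequence:
    """Return a copy of ``seq`` with artifacts added to selected frames.

    severity 0 returns the input values unchanged bit-exactly. The fraction
    of modified pixels grows monotonically with severity (nested level sets
    of a fixed smooth field). Deterministic for a fixed seed.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"kind must be one of {ARTIFACT_KINDS}")
    out = seq.copy()
    if severity == 0.0:
        return out
    t_all = range(seq.n_frames)
    frames_affected = list(t_all) if frames_affected is None else sorted(frames_affected)

    rng = np.random.default_rng(seed)
    h, w = seq.frames.shape[1:]
    field = _ndi.gaussian_filter(rng.normal(0, 1, size=(h, w)), sigma=max(h, w) / 12.0)
    # rank-normalise so the sub-level set at q covers exactly ~q of the pixels
    order = np.argsort(field, axis=None)
    quantile = np.empty(field.size)
    quantile[order] = np.arange(field.size) / (field.size - 1)
    quantile = quantile.reshape(field.shape)
    region = quantile < severity

    ghost = _ndi.gaussian_filter(rng.normal(0, 1, size=(h, w)), sigma=max(h, w) / 20.0)
    ghost = 0.5 * ghost / max(np.abs(ghost).max(), 1e-9)

    for t in frames_affected:
        if not 0 <= t < seq.n_frames:
            raise ValueError(f"frame index {t} out of range")
        img = out.frames[t]
        if kind == "subtraction_ghost":
            img[region] = np.clip(img[region] + severity * ghost[region], 0.0, 1.0)
        else:  # motion: blend with a shifted copy inside the region
            shift = 2.0 + 6.0 * severity
            shifted = _ndi.shift(img, (shift, 0.4 * shift), order=1, mode="nearest")
            img[region] = np.clip(
                (1 - 0.5 * severity) * img[region] + 0.5 * severity * shifted[region],
                0.0,
                1.0,
            )
    return out
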