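"""Quantitative evaluation: SSIM/PSNR/MSE with bootstrap CIs, residual
maps, time-intensity-curve error, and guidewire tip localization error."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi
from skimage.metrics import structural_similarity
from skimage.morphology import skeletonize

#: canonical Gaussian-window SSIM constants (window 11, sigma 1.5)
SSIM_KWARGS = dict(
    win_size=11, gaussian_weights=True, sigma=1.5, K1=0.01, K2=0.03,
    use_sample_covariance=False, data_range=1.0,
)


@dataclass
class MetricReport:
    ssim_mean: float
    ssim_ci: tuple[float, float]
    psnr_mean: float
    psnr_ci: tuple[float, float]
    mse_mean: float
    per_sequence: list[dict]

    @property
    def n_sequences(self) -> int:
        return len(self.per_sequence)

    def to_dict(self) -> dict:
        return {
            "ssim": {"mean": self.ssim_mean, "ci95": list(self.ssim_ci)},
            "psnr_db": {"mean": self.psnr_mean, "ci95": list(self.psnr_ci)},
            "mse": {"mean": self.mse_mean},
            "n_sequences": self.n_sequences,
            "per_sequence": self.per_sequence,
        }


def compute_image_metrics(gen: np.ndarray, real: np.ndarray) -> tuple[float, float, float]:
    """(SSIM, PSNR dB, MSE) between two frames with values in [0, 1].

    PSNR uses peak 1.0 and equals -10 log10(MSE); identical frames give
    (1, inf, 0).
    """
    gen = np.asarray(gen, dtype=np.float64)
    real = np.asarray(real, dtype=np.float64)
    if gen.shape != real.shape:
        raise ValueError("frames must share a shape")
    mse = float(np.mean((gen - real) ** 2))
    psnr = float("inf") if mse == 0.0 else -10.0 * np.log10(mse)
    ssim = float(structural_similarity(gen, real, **SSIM_KWARGS))
    return ssim, psnr, mse


def sequence_metrics(gen_frames: np.ndarray, real_frames: np.ndarray) -> dict:
    """Mean per-frame metrics for one sequence pair in [0, 1]."""
    vals = [compute_image_metrics(g, r) for g, r in zip(gen_frames, real_frames)]
    ssim, psnr, mse = zip(*vals)
    finite_psnr = [p for p in psnr if np.isfinite(p)]
    return {
        "ssim": float(np.mean(ssim)),
        "psnr_db": float(np.mean(finite_psnr)) if finite_psnr else float("inf"),
        "mse": float(np.mean(mse)),
        "per_frame_ssim": list(map(float, ssim)),
    }


def bootstrap_ci(
    values, level: float = 0.95, reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean, resampling sequences."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    means = values[idx].mean(axis=1)
    lo = float(np.quantile(means, (1 - level) / 2))
    hi = float(np.quantile(means, 1 - (1 - level) / 2))
    return lo, hi


def metric_report(
    gen_sequences: list[np.ndarray],
    real_sequences: list[np.ndarray],
    seed: int = 0,
) -> MetricReport:
    per_seq = [sequence_metrics(g, r) for g, r in zip(gen_sequences, real_sequences)]
    ssims = [d["ssim"] for d in per_seq]
    psnrs = [d["psnr_db"] for d in per_seq]
    mses = [d["mse"] for d in per_seq]
    if len(per_seq) >= 2:
        ssim_ci = bootstrap_ci(ssims, seed=seed)
        psnr_ci = bootstrap_ci(psnrs, seed=seed + 1)
    else:
        ssim_ci = (ssims[0], ssims[0])
        psnr_ci = (psnrs[0], psnrs[0])
    return MetricReport(
        ssim_mean=float(np.mean(ssims)),
        ssim_ci=ssim_ci,
        psnr_mean=float(np.mean(psnrs)),
        psnr_ci=psnr_ci,
        mse_mean=float(np.mean(mses)),
        per_sequence=per_seq,
    )


def residual_map(gen: np.ndarray, real: np.ndarray, amplify: float = 10.0):
    """|gen - real| plus the amplified display variant min(k |gen-real|, 1)."""
    gen = np.asarray(gen, dtype=np.float64)
    real = np.asarray(real, dtype=np.float64)
    if gen.shape != real.shape:
        raise ValueError("frames must share a shape")
    res = np.abs(gen - real)
    return res, np.minimum(amplify * res, 1.0)


def _minmax01(series: np.ndarray) -> np.ndarray:
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.zeros_like(series)
    return (series - lo) / (hi - lo)


def time_intensity_error(
    gen_seq: np.ndarray, real_seq: np.ndarray, pixels: list[tuple[int, int]]
) -> float:
    """Max abs deviation between per-pixel TICs after [0, 1] normalization.

    Each pixel's temporal series is min-max normalized independently per
    sequence, so per-pixel affine intensity distortions cancel exactly.
    """
    gen_seq = np.asarray(gen_seq, dtype=np.float64)
    real_seq = np.asarray(real_seq, dtype=np.float64)
    if gen_seq.shape[0] != real_seq.shape[0]:
        raise ValueError("sequences must have the same length")
    worst = 0.0
    for r, c in pixels:
        if not (0 <= r < gen_seq.shape[1] and 0 <= c < gen_seq.shape[2]):
            raise ValueError(f"pixel ({r}, {c}) out of bounds")
        g = _minmax01(gen_seq[:, r, c])
        t = _minmax01(real_seq[:, r, c])
        worst = max(worst, float(np.max(np.abs(g - t))))
    return worst


# ---------------------------------------------------------------------------
# guidewire tip localization


def locate_wire_tip(frame: np.ndarray, dark_fraction: float = 0.35) -> tuple[float, float] | None:
    """Tip of the darkest curvilinear structure in a light-background frame.

    Pixels darker than min + dark_fraction * range are kept, the largest
    connected component is skeletonized, and the tip is the skeleton
    endpoint farthest from the image border (the wire enters from an edge).
    Returns None when no curvilinear structure is found.
    """
    frame = np.asarray(frame, dtype=np.float64)
    lo, hi = frame.min(), frame.max()
    if hi - lo < 1e-6:
        return None
    mask = frame <= lo + dark_fraction * (hi - lo)
    if mask.sum() < 8:
        return None
    labels, n = _ndi.label(mask)
    if n == 0:
        return None
    sizes = _ndi.sum(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    skel = skeletonize(mask)
    if skel.sum() < 3:
        return None
    neighbours = _ndi.convolve(skel.astype(int), np.ones((3, 3), dtype=int), mode="constant")
    endpoints = np.argwhere(skel & (neighbours == 2))  # self + exactly one neighbour
    if len(endpoints) == 0:
        return None
    h, w = frame.shape
    border_d = np.minimum.reduce(
        [endpoints[:, 0], endpoints[:, 1], h - 1 - endpoints[:, 0], w - 1 - endpoints[:, 1]]
    )
    tip = endpoints[int(np.argmax(border_d))].astype(float)
    # skeletonization retracts endpoints by about the structure half-width;
    # extend along the local skeleton direction while the mask stays dark
    trace = [tip.copy()]
    visited = {(int(tip[0]), int(tip[1]))}
    cur = (int(tip[0]), int(tip[1]))
    for _ in range(4):
        nxt = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                cand = (cur[0] + dr, cur[1] + dc)
                if cand in visited or not (0 <= cand[0] < h and 0 <= cand[1] < w):
                    continue
                if skel[cand]:
                    nxt = cand
                    break
            if nxt:
                break
        if nxt is None:
            break
        visited.add(nxt)
        trace.append(np.array(nxt, dtype=float))
        cur = nxt
    if len(trace) > 1:
        direction = trace[0] - trace[-1]
        norm = np.linalg.norm(direction)
        if norm > 0:
            direction /= norm
            half_width = float(_ndi.distance_transform_edt(mask)[int(tip[0]), int(tip[1])])
            probe = tip.copy()
            for _ in range(24):
                cand = probe + 0.25 * direction
                ri, ci = int(round(cand[0])), int(round(cand[1]))
                if not (0 <= ri < h and 0 <= ci < w) or not mask[ri, ci]:
                    break
                probe = cand
            # the cap of the dark structure extends one half-width past the
            # true tip centre
            tip = probe - direction * max(half_width - 0.5, 0.0)
    return float(tip[0]), float(tip[1])


def guidewire_tip_error(gen_seq: np.ndarray, real_tip_xy: np.ndarray) -> dict:
    """Per-frame Euclidean tip displacement against ground-truth tips.

    Frames where no curvilinear structure is detected are flagged and
    excluded from the mean but counted.
    """
    gen_seq = np.asarray(gen_seq, dtype=np.float64)
    real_tip_xy = np.asarray(real_tip_xy, dtype=np.float64)
    errors, flagged = [], []
    for t in range(gen_seq.shape[0]):
        tip = locate_wire_tip(gen_seq[t])
        if tip is None:
            flagged.append(t)
            errors.append(np.nan)
        else:
            errors.append(float(np.hypot(tip[0] - real_tip_xy[t, 0], tip[1] - real_tip_xy[t, 1])))
    valid = [e for e in errors if np.isfinite(e)]
    return {
        "per_frame": errors,
        "flagged_frames": flagged,
        "max": float(np.max(valid)) if valid else None,
        "mean": float(np.mean(valid)) if valid else None,
        "n_flagged": len(flagged),
    }
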