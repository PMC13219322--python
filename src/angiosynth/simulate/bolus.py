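"""Contrast bolus dynamics: gamma-variate opacity curves per segment."""

from __future__ import annotations

import numpy as np

from angiosynth.simulate.tree import VesselTree


def gamma_variate(t: np.ndarray, t0: float, t_peak: float, alpha: float) -> np.ndarray:
    """Peak-normalised gamma-variate bolus curve.

    c(t) = ((t - t0)/tp)^alpha * exp(alpha * (1 - (t - t0)/tp)) for t > t0,
    0 otherwise. The maximum value 1 is attained exactly at t = t0 + tp.
    """
    t = np.asarray(t, dtype=np.float64)
    tau = (t - t0) / t_peak
    out = np.zeros_like(t)
    pos = tau > 0
    out[pos] = tau[pos] ** alpha * np.exp(alpha * (1.0 - tau[pos]))
    return out


def simulate_bolus(
    tree: VesselTree,
    t_peak: float = 6.0,
    alpha: float = 2.5,
    n_frames: int = 24,
) -> np.ndarray:
    """Per-segment opacity series over ``n_frames`` frames.

    Each segment's opacity is a gamma-variate delayed by the segment's bolus
    arrival time, peak-normalised to 1.

    Returns
    -------
    (n_segments, n_frames) array of opacities in [0, 1].
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if t_peak <= 0 or alpha <= 0:
        raise ValueError("t_peak and alpha must be positive")
    t = np.arange(n_frames, dtype=np.float64)
    out = np.empty((tree.n_segments, n_frames))
    for i in range(tree.n_segments):
        out[i] = gamma_variate(t, float(tree.arrival_time[i]), t_peak, alpha)
    return out
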