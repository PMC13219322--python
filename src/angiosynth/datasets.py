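"""Programmatic dataset generation: simulator sequences ready for training
and evaluation (frames normalized to [-1, 1])."""

from __future__ import annotations

import numpy as np

from angiosynth.preprocess import normalize_sequence
from angiosynth.simulate import (
    MORPHOLOGY_CLASSES,
    generate_vessel_tree,
    render_sequence,
    simulate_bolus,
)
from angiosynth.types import FrameSequence


def make_sequence(
    seed: int,
    resolution: int = 64,
    n_frames: int = 24,
    mode: str = "2d",
    morphology: str = "normal",
    n_branches: int = 9,
    guidewire: bool = False,
    noise_sigma: float = 0.008,
    normalize: bool = True,
    per_frame: bool = False,
    vessel_contrast: float = 1.0,
):
    """One rendered sequence plus its ground truth.

    ``vessel_contrast`` scales the bolus opacity; guidewire scenarios use a
    low value so the wire is the dominant dark structure.
    """
    rng = np.random.default_rng(seed)
    tree = generate_vessel_tree(
        seed=int(rng.integers(2**31)), n_branches=n_branches,
        morphology_class=morphology, domain_px=resolution,
    )
    t_peak = float(rng.uniform(4.0, 7.0))
    alpha = float(rng.uniform(1.8, 3.2))
    opacity = simulate_bolus(tree, t_peak=t_peak, alpha=alpha, n_frames=n_frames)
    opacity = opacity * vessel_contrast
    seq, gt = render_sequence(
        tree, opacity, n_frames, mode=mode, resolution=resolution,
        guidewire=guidewire, seed=int(rng.integers(2**31)), noise_sigma=noise_sigma,
    )
    if normalize:
        seq.frames = normalize_sequence(seq.frames, per_frame=per_frame)
    return seq, gt


def generate_dataset(
    n_sequences: int,
    resolution: int = 64,
    n_frames: int = 24,
    seed: int = 0,
    p_3d: float = 0.5,
    morphologies: tuple = MORPHOLOGY_CLASSES,
    exclude_morphologies: tuple = (),
    noise_sigma: float = 0.008,
) -> list[FrameSequence]:
    """A list of normalized sequences with mixed modes and morphologies.

    ``exclude_morphologies`` supports held-out-category experiments: the
    named classes are never generated.
    """
    allowed = [m for m in morphologies if m not in exclude_morphologies]
    if not allowed:
        raise ValueError("no morphology classes left after exclusion")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_sequences):
        mode = "3d" if rng.random() < p_3d else "2d"
        morph = allowed[int(rng.integers(len(allowed)))]
        seq, _ = make_sequence(
            seed=int(rng.integers(2**31)),
            resolution=resolution,
            n_frames=n_frames,
            mode=mode,
            morphology=morph,
            noise_sigma=noise_sigma,
        )
        out.append(seq)
    return out
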