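"""Shared fixtures: seeded data and session-scoped trained models.

Training runs are scaled down to fit a single-CPU budget; the session-scoped
models are shared between the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from angiosynth.datasets import generate_dataset, make_sequence
from angiosynth.nn.model import FrameSynthesisModel, ModelConfig
from angiosynth.training import TrainConfig, train_model

TRAIN_RESOLUTION = 64
TRAIN_SEED = 11


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bolus_train_data():
    """~200 synthetic sequences for the main tiny training run."""
    return generate_dataset(
        200, resolution=TRAIN_RESOLUTION, n_frames=29, seed=TRAIN_SEED, p_3d=0.6
    )


@pytest.fixture(scope="session")
def trained_tiny(bolus_train_data):
    """The main scaled-down training run (base 8 channels, 64x64, 30 epochs).

    batches_per_epoch caps the work per epoch so the run fits the CPU
    budget; the sample pool still covers all 200 sequences.
    """
    model = FrameSynthesisModel(ModelConfig(base_channels=8, n_scales=3, seed=0))
    cfg = TrainConfig(
        lr_init=3e-4,
        total_epochs=30,
        phase1_epochs=30,
        cosine_period=50,
        batch_size=8,
        seed=0,
        n_generated=6,
        batches_per_epoch=10,
    )
    model, history = train_model(model, bolus_train_data, cfg)
    return model, history, cfg


@pytest.fixture(scope="session")
def heldout_sequences():
    """20 held-out synthetic sequences (seed disjoint from training)."""
    return generate_dataset(
        20, resolution=TRAIN_RESOLUTION, n_frames=29, seed=999, p_3d=0.6
    )


def _translation_pairs(n: int, size: int, shift: float, seed: int):
    """Smooth random textures paired with copies shifted by ``shift`` px."""
    from scipy import ndimage as _ndi

    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n):
        base = _ndi.gaussian_filter(rng.normal(0, 1, size=(size, size + 16)), 3.0)
        base = 2.0 * (base - base.min()) / (base.max() - base.min()) - 1.0
        f0 = base[:, 8 : 8 + size]
        fm = base[:, 8 + int(round(shift / 2)) : 8 + int(round(shift / 2)) + size]
        f1 = base[:, 8 + int(round(shift)) : 8 + int(round(shift)) + size]
        seqs.append(np.stack([f0, fm, f1]).astype(np.float32))
    return seqs


@pytest.fixture(scope="session")
def translation_model():
    """Tiny reference model trained on pure-translation pairs (shift 3 px)."""
    seqs = _translation_pairs(32, 32, shift=3.0, seed=5)
    model = FrameSynthesisModel(
        ModelConfig(base_channels=8, n_scales=2, seed=1, use_attention=False)
    )
    cfg = TrainConfig(
        lr_init=1e-3,
        total_epochs=40,
        phase1_epochs=40,
        batch_size=8,
        seed=2,
        n_generated=1,
        batches_per_epoch=4,
    )
    model, _ = train_model(model, seqs, cfg)
    return model, seqs


@pytest.fixture(scope="session")
def static_model():
    """Tiny model trained on static scenes (frame0 == target == frame1)."""
    from scipy import ndimage as _ndi

    rng = np.random.default_rng(7)
    seqs = []
    for _ in range(24):
        base = _ndi.gaussian_filter(rng.normal(0, 1, size=(32, 32)), 2.5)
        base = 2.0 * (base - base.min()) / (base.max() - base.min()) - 1.0
        seqs.append(np.stack([base] * 3).astype(np.float32))
    model = FrameSynthesisModel(
        ModelConfig(base_channels=8, n_scales=2, seed=3, use_attention=False)
    )
    cfg = TrainConfig(
        lr_init=1e-3,
        total_epochs=30,
        phase1_epochs=30,
        batch_size=8,
        seed=4,
        n_generated=1,
        batches_per_epoch=3,
    )
    model, _ = train_model(model, seqs, cfg)
    return model


@pytest.fixture(scope="session")
def constant_model():
    """Tiny model trained on constant sequences of varied grey levels."""
    rng = np.random.default_rng(21)
    seqs = [
        np.full((3, 32, 32), rng.uniform(-0.8, 0.8), dtype=np.float32)
        for _ in range(24)
    ]
    model = FrameSynthesisModel(
        ModelConfig(base_channels=8, n_scales=2, seed=6, use_attention=False)
    )
    cfg = TrainConfig(
        lr_init=1e-3,
        total_epochs=20,
        phase1_epochs=20,
        batch_size=8,
        seed=7,
        n_generated=1,
        batches_per_epoch=3,
    )
    model, _ = train_model(model, seqs, cfg)
    return model


@pytest.fixture()
def wire_sequence():
    """2d guidewire scenario with faint vessels and tip ground truth."""
    seq, gt = make_sequence(
        seed=42, resolution=96, n_frames=20, mode="2d", morphology="normal",
        guidewire=True, normalize=False, vessel_contrast=0.15,
    )
    return seq, gt
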