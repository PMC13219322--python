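"""Single-file model checkpoints: config + weights + schedule state (.npz)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from angiosynth.nn.model import FrameSynthesisModel, ModelConfig


def save_checkpoint(
    model: FrameSynthesisModel,
    path: str | Path,
    epoch: int = 0,
    extra: dict | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param:{name}": p.data for name, p in model.named_parameters()}
    meta = {
        "config": model.config.to_dict(),
        "epoch": epoch,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[FrameSynthesisModel, dict]:
    with np.load(Path(path)) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        model = FrameSynthesisModel(ModelConfig.from_dict(meta["config"]))
        params = dict(model.named_parameters())
        for key in archive.files:
            if not key.startswith("param:"):
                continue
            name = key[len("param:"):]
            if name not in params:
                raise ValueError(f"checkpoint parameter {name!r} not in model")
            if params[name].data.shape != archive[key].shape:
                raise ValueError(f"shape mismatch for {name!r}")
            params[name].data = archive[key].copy()
    return model, meta
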