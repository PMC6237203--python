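"""Model checkpointing: parameter arrays (npz) + a JSON config manifest.

The manifest records the architecture config, the class encodings and the
training-set score standardization, so a checkpoint is self-describing;
parameters are stored in the deterministic order the model enumerates
them.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .model import FusionConfig, FusionModel


def _all_params(model: FusionModel):
    return model.stage1_params() + model.stage2_params(include_cnn=False)


def save_model(model: FusionModel, out_dir: str | Path) -> Path:
    """Write ``config.json`` + ``params.npz`` (+ score standardization)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(model.config)}
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(_all_params(model))}
    if model.score_mean is not None:
        arrays["score_mean"] = model.score_mean
        arrays["score_sd"] = model.score_sd
    np.savez(out / "params.npz", **arrays)
    (out / "config.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def load_model(model_dir: str | Path) -> FusionModel:
    """Rebuild a model from a checkpoint directory."""
    mdir = Path(model_dir)
    manifest = json.loads((mdir / "config.json").read_text())
    cfg = manifest["config"]
    for key in ("mlp_hidden", "primary_classes", "sum_classes"):
        cfg[key] = tuple(cfg[key])
    config = FusionConfig(**cfg)
    model = FusionModel(config, np.random.default_rng(config.seed))
    with np.load(mdir / "params.npz") as data:
        for i, p in enumerate(_all_params(model)):
            arr = data[f"p{i:04d}"]
            if arr.shape != p.value.shape:
                raise ValueError("checkpoint does not match the configured "
                                 "architecture")
            p.value[...] = arr
        if "score_mean" in data:
            model.score_mean = data["score_mean"]
            model.score_sd = data["score_sd"]
    return model
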