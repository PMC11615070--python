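"""TOML configuration files for models and training.

Layout::

    [model]
    strategy = "inter"
    head_hidden = 16
    seed = 0

    [branch]
    base_channels = 16
    n_blocks = 4
    norm = "instance"

    [branch.meg]
    stem_stride = [1, 2]
    time_strides = [2, 2, 2, 4]

    [branch.mri]
    stem_stride = 2
    strides = [2, 2, 1, 1]

    [sccaf]
    pool_2d = [64, 64]
    pool_3d = [16, 16, 16]
    heads = 1
    positional_embedding = true
    weight_shape = "per_token"

    [train]
    lr = 0.001
    batch_size = 2
    epochs = 100
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .backbones import BranchConfig
from .models import ModelConfig
from .sccaf import SCCAFConfig
from .train_eval import TrainConfig


def _load(path) -> dict:
    with open(Path(path), "rb") as f:
        return tomllib.load(f)


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def model_config_from_dict(doc: dict) -> ModelConfig:
    branch = dict(doc.get("branch", {}))
    meg = branch.pop("meg", {})
    mri = branch.pop("mri", {})
    if "stem_stride" in meg:
        branch["meg_stem_stride"] = meg["stem_stride"]
    if "time_strides" in meg:
        branch["meg_time_strides"] = meg["time_strides"]
    if "stem_stride" in mri:
        branch["mri_stem_stride"] = mri["stem_stride"]
    if "strides" in mri:
        branch["mri_strides"] = mri["strides"]
    cfg = dict(doc.get("model", {}))
    cfg["branch"] = BranchConfig(**_tupled(branch))
    cfg["sccaf"] = SCCAFConfig(**_tupled(doc.get("sccaf", {})))
    return ModelConfig(**cfg)


def load_model_config(path) -> ModelConfig:
    return model_config_from_dict(_load(path))


def load_train_config(path) -> TrainConfig:
    return TrainConfig(**_load(path).get("train", {}))
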