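"""The five classification models: two unimodal CNNs and three fusion
strategies (early, intermediate via SCCAF, late/decision-level).

Every classifier head is adaptive-pool-to-a-token-grid -> flatten -> linear
-> ReLU -> linear; softmax lives inside the loss, models emit logits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .backbones import BranchConfig, MEGBranch, MRIBranch, ResBlock, reduced_branch_config
from .nn import (
    AdaptiveAvgPool, Conv2d, Flatten, Linear, Module, ReLU, Sequential,
    make_norm, softmax,
)
from .sccaf import SCCAFConfig, SCCAFModule, reduced_sccaf_config

STRATEGIES = ("meg_only", "mri_only", "early", "inter", "late")


@dataclass
class ModelConfig:
    strategy: str = "inter"
    branch: BranchConfig = field(default_factory=BranchConfig)
    sccaf: SCCAFConfig = field(default_factory=SCCAFConfig)
    n_classes: int = 2
    head_hidden: int = 16
    early_mode: str = "2d"  # or "3d" (broadcast MEG along the z axis)
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if self.early_mode not in ("2d", "3d"):
            raise ValueError("early_mode must be '2d' or '3d'")


def reduced_model_config(strategy: str = "inter", norm: str = "batch",
                         seed: int = 0) -> ModelConfig:
    """Small configuration matched to 16x512 MEG / 24^3 MRI inputs."""
    return ModelConfig(strategy=strategy, branch=reduced_branch_config(norm),
                       sccaf=reduced_sccaf_config(), seed=seed)


def _pool_head(channels, pool_size, hidden, n_classes, rng) -> Sequential:
    P = int(np.prod(pool_size))
    return Sequential(
        AdaptiveAvgPool(pool_size),
        Flatten(),
        Linear(P * channels, hidden, rng=rng),
        ReLU(),
        Linear(hidden, n_classes, rng=rng),
    )


def _token_head(channels, tokens, hidden, n_classes, rng) -> Sequential:
    return Sequential(
        Flatten(),
        Linear(tokens * channels, hidden, rng=rng),
        ReLU(),
        Linear(hidden, n_classes, rng=rng),
    )


def _as_batched(x, ndim, name):
    if x is None:
        raise ValueError(f"strategy requires the {name} modality, got None")
    x = np.asarray(x)
    if x.ndim == ndim + 1:  # (B, *spatial) -> (B, 1, *spatial)
        x = x[:, None]
    if x.ndim != ndim + 2:
        raise ValueError(f"bad {name} input shape {x.shape}")
    return x


class FusionModel(Module):
    """Common interface: forward(meg, mri) -> logits (B, n_classes)."""

    strategy: str

    def forward(self, meg, mri):  # pragma: no cover - abstract
        raise NotImplementedError


class UnimodalModel(FusionModel):
    def __init__(self, cfg: ModelConfig, modality: str, rng):
        self.strategy = f"{modality}_only"
        self.modality = modality
        C = cfg.branch.base_channels
        if modality == "meg":
            self.branch = MEGBranch(cfg.branch, rng)
            pool = cfg.sccaf.pool_2d
        else:
            self.branch = MRIBranch(cfg.branch, rng)
            pool = cfg.sccaf.pool_3d
        self.head = _pool_head(C, pool, cfg.head_hidden, cfg.n_classes, rng)

    def forward(self, meg, mri):
        if self.modality == "meg":
            x = _as_batched(meg, 2, "MEG")
        else:
            x = _as_batched(mri, 3, "MRI")
        return self.head(self.branch(x))

    def backward(self, dlogits):
        return self.branch.backward(self.head.backward(dlogits))


class InterFusionModel(FusionModel):
    strategy = "inter"

    def __init__(self, cfg: ModelConfig, rng):
        C = cfg.branch.base_channels
        self.meg_branch = MEGBranch(cfg.branch, rng)
        self.mri_branch = MRIBranch(cfg.branch, rng)
        self.sccaf = SCCAFModule(C, cfg.sccaf, rng)
        self.head = _token_head(C, cfg.sccaf.tokens, cfg.head_hidden,
                                cfg.n_classes, rng)

    def forward(self, meg, mri):
        f_meg = self.meg_branch(_as_batched(meg, 2, "MEG"))
        f_mri = self.mri_branch(_as_batched(mri, 3, "MRI"))
        fused = self.sccaf(f_meg, f_mri)
        return self.head(fused)

    def backward(self, dlogits):
        dfused = self.head.backward(dlogits)
        df_meg, df_mri = self.sccaf.backward(dfused)
        return self.meg_branch.backward(df_meg), self.mri_branch.backward(df_mri)


class LateFusionModel(FusionModel):
    strategy = "late"

    def __init__(self, cfg: ModelConfig, rng):
        C = cfg.branch.base_channels
        self.meg_branch = MEGBranch(cfg.branch, rng)
        self.mri_branch = MRIBranch(cfg.branch, rng)
        self.meg_head = _pool_head(C, cfg.sccaf.pool_2d, cfg.head_hidden,
                                   cfg.n_classes, rng)
        self.mri_head = _pool_head(C, cfg.sccaf.pool_3d, cfg.head_hidden,
                                   cfg.n_classes, rng)
        self.final = Linear(2 * cfg.n_classes, cfg.n_classes, rng=rng)
        self.n_classes = cfg.n_classes

    def forward(self, meg, mri):
        za = self.meg_head(self.meg_branch(_as_batched(meg, 2, "MEG")))
        zb = self.mri_head(self.mri_branch(_as_batched(mri, 3, "MRI")))
        return self.final(np.concatenate([za, zb], axis=-1))

    def backward(self, dlogits):
        d = self.final.backward(dlogits)
        da, db = d[:, : self.n_classes], d[:, self.n_classes:]
        gm = self.meg_branch.backward(self.meg_head.backward(da))
        gv = self.mri_branch.backward(self.mri_head.backward(db))
        return gm, gv


class EarlyFusionModel(FusionModel):
    """Input-level fusion: both modalities resampled to one grid and stacked
    as channels before a single shared backbone.

    In 2d mode the MEG sensor-time image is resized to the volume's in-plane
    grid and the volume is mean-projected along z; in 3d mode the resized MEG
    image is broadcast along z and fused as a second 3D channel.
    """

    strategy = "early"

    def __init__(self, cfg: ModelConfig, rng):
        C = cfg.branch.base_channels
        self.mode = cfg.early_mode
        if self.mode == "2d":
            self.stem = Sequential(
                Conv2d(2, C, 7, stride=2, padding=3, rng=rng),
                make_norm(cfg.branch.norm, C),
                ReLU(),
            )
            self.blocks = [
                ResBlock(2, C, C, s, cfg.branch.norm, rng)
                for s in cfg.branch.mri_strides
            ]
            self.head = _pool_head(C, cfg.sccaf.pool_3d[:2], cfg.head_hidden,
                                   cfg.n_classes, rng)
        else:
            self.backbone3d = MRIBranch(cfg.branch, rng, in_ch=2)
            self.head = _pool_head(C, cfg.sccaf.pool_3d, cfg.head_hidden,
                                   cfg.n_classes, rng)

    @staticmethod
    def _resize2d(batch, grid):
        out = np.empty((batch.shape[0],) + tuple(grid), dtype=np.float32)
        factors = (grid[0] / batch.shape[1], grid[1] / batch.shape[2])
        for i, img in enumerate(batch):
            out[i] = ndimage.zoom(img, factors, order=1, grid_mode=True,
                                  mode="nearest")
        return out

    def fuse_inputs(self, meg, mri):
        meg = _as_batched(meg, 2, "MEG")[:, 0]
        mri = _as_batched(mri, 3, "MRI")[:, 0]
        grid = mri.shape[1:3]
        meg_img = self._resize2d(meg, grid)
        if self.mode == "2d":
            mri_img = mri.mean(axis=3)
            return np.stack([meg_img, mri_img], axis=1)
        z = mri.shape[3]
        meg_vol = np.repeat(meg_img[..., None], z, axis=3)
        return np.stack([meg_vol, mri], axis=1)

    def forward(self, meg, mri):
        x = self.fuse_inputs(meg, mri)
        if self.mode == "2d":
            h = self.stem(x)
            for b in self.blocks:
                h = b(h)
            return self.head(h)
        return self.head(self.backbone3d(x))

    def backward(self, dlogits):
        # input resizing is data preparation; gradients stop at the stem
        g = self.head.backward(dlogits)
        if self.mode == "2d":
            for b in reversed(self.blocks):
                g = b.backward(g)
            return self.stem.backward(g)
        return self.backbone3d.backward(g)


def build_model(cfg: ModelConfig) -> FusionModel:
    rng = np.random.default_rng(cfg.seed)
    if cfg.strategy == "meg_only":
        return UnimodalModel(cfg, "meg", rng)
    if cfg.strategy == "mri_only":
        return UnimodalModel(cfg, "mri", rng)
    if cfg.strategy == "inter":
        return InterFusionModel(cfg, rng)
    if cfg.strategy == "late":
        return LateFusionModel(cfg, rng)
    if cfg.strategy == "early":
        return EarlyFusionModel(cfg, rng)
    raise ValueError(f"unknown strategy {cfg.strategy!r}")


def predict_proba(model: FusionModel, meg, mri) -> np.ndarray:
    """Class probabilities in eval mode (deterministic, no caching)."""
    was_training = model.training
    model.eval()
    try:
        logits = model.forward(meg, mri)
    finally:
        model.train(was_training)
    return softmax(np.asarray(logits, dtype=np.float64))


# -- checkpointing ----------------------------------------------------------

def config_to_dict(cfg: ModelConfig) -> dict:
    return dataclasses.asdict(cfg)

def config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    br = d.get("branch", {})
    sc = d.get("sccaf", {})
    branch = BranchConfig(**{**br, **{
        k: tuple(v) for k, v in br.items() if isinstance(v, list)
    }})
    sccaf = SCCAFConfig(**{**sc, **{
        k: tuple(v) for k, v in sc.items() if isinstance(v, list)
    }})
    d["branch"], d["sccaf"] = branch, sccaf
    return ModelConfig(**d)


def save_checkpoint(model: FusionModel, cfg: ModelConfig, path) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(model.state_list())}
    np.savez(path, __config__=json.dumps(config_to_dict(cfg)), **arrays)


def load_checkpoint(path) -> tuple[FusionModel, ModelConfig]:
    with np.load(path, allow_pickle=False) as archive:
        cfg = config_from_dict(json.loads(str(archive["__config__"])))
        model = build_model(cfg)
        n = len([k for k in archive.files if k.startswith("p")])
        model.load_state_list([archive[f"p{i}"] for i in range(n)])
    return model, cfg
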