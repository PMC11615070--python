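"""Modality-specific CNN feature extractors.

The MEG branch opens with a 1x15 strip convolution applied along time within
each sensor row, then a 3x3 convolution mixing adjacent sensor rows; residual
blocks afterwards stride only the time axis (sensor axis stays 102), taking
8192 samples down to 128. The MRI branch opens with a 7x7x7 stem and
downsamples isotropically from 192^3 to 24^3. Channel width C is constant
through both branches so the branch outputs are exactly (C, 102, 128) and
(C, 24, 24, 24) for any configured C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, Conv3d, Module, ReLU, Sequential, make_norm


@dataclass
class BranchConfig:
    """Configuration shared by both feature-extraction branches.

    Stride schedules are per-block; their product (times the stem stride)
    sets the total downsampling: 64 along MEG time (8192 -> 128) and 8 per
    MRI axis (192 -> 24) at the default full-resolution settings.
    """

    base_channels: int = 16
    n_blocks: int = 4
    norm: str = "instance"
    meg_stem_stride: tuple[int, int] = (1, 2)
    meg_time_strides: tuple[int, ...] = (2, 2, 2, 4)
    mri_stem_stride: int = 2
    mri_strides: tuple[int, ...] = (2, 2, 1, 1)

    def __post_init__(self):
        if self.base_channels <= 0 or self.n_blocks <= 0:
            raise ValueError("base_channels and n_blocks must be positive")
        if len(self.meg_time_strides) != self.n_blocks:
            raise ValueError("meg_time_strides must have n_blocks entries")
        if len(self.mri_strides) != self.n_blocks:
            raise ValueError("mri_strides must have n_blocks entries")

    @property
    def meg_time_downsampling(self) -> int:
        return self.meg_stem_stride[1] * int(np.prod(self.meg_time_strides))

    @property
    def mri_downsampling(self) -> int:
        return self.mri_stem_stride * int(np.prod(self.mri_strides))


def reduced_branch_config(norm: str = "batch") -> BranchConfig:
    """Small-footprint configuration for 16x512 MEG and 24^3 MRI inputs.

    Batch norm is the default here: per-sample normalization (instance/group)
    cancels the very channel-energy contrasts that carry band-power effects,
    which only matters once feature maps are this small and training this
    short.
    """
    return BranchConfig(base_channels=8, n_blocks=2, norm=norm,
                        meg_stem_stride=(1, 2), meg_time_strides=(2, 2),
                        mri_stem_stride=2, mri_strides=(2, 1))


def conv_out_len(n: int, kernel: int, stride: int, padding: int) -> int:
    return (n + 2 * padding - kernel) // stride + 1


class ResBlock(Module):
    """conv-norm-ReLU-conv-norm plus (projected) identity, then ReLU."""

    def __init__(self, ndim: int, in_ch: int, out_ch: int, stride, norm: str,
                 rng: np.random.Generator):
        Conv = Conv2d if ndim == 2 else Conv3d
        stride_t = stride if isinstance(stride, tuple) else (stride,) * ndim
        self.conv1 = Conv(in_ch, out_ch, 3, stride=stride_t, padding=1, rng=rng)
        self.norm1 = make_norm(norm, out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv(out_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.norm2 = make_norm(norm, out_ch)
        self.relu_out = ReLU()
        if in_ch != out_ch or any(s != 1 for s in stride_t):
            self.shortcut = Sequential(
                Conv(in_ch, out_ch, 1, stride=stride_t, padding=0, bias=False, rng=rng),
                make_norm(norm, out_ch),
            )
        else:
            self.shortcut = None

    def forward(self, x):
        h = self.relu1(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        s = x if self.shortcut is None else self.shortcut(x)
        return self.relu_out(h + s)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gh = self.norm2.backward(g)
        gh = self.conv2.backward(gh)
        gh = self.relu1.backward(gh)
        gh = self.norm1.backward(gh)
        gx = self.conv1.backward(gh)
        gx = gx + (g if self.shortcut is None else self.shortcut.backward(g))
        return gx


class MEGBranch(Module):
    """2D branch over sensors x time; strides act on the time axis only."""

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator | None = None,
                 in_ch: int = 1):
        if rng is None:
            rng = np.random.default_rng(0)
        C = cfg.base_channels
        self.cfg = cfg
        self.stem = Sequential(
            Conv2d(in_ch, C, (1, 15), stride=cfg.meg_stem_stride, padding=(0, 7),
                   rng=rng),
            make_norm(cfg.norm, C),
            ReLU(),
            Conv2d(C, C, 3, stride=1, padding=1, rng=rng),
            make_norm(cfg.norm, C),
            ReLU(),
        )
        self.blocks = [
            ResBlock(2, C, C, (1, s), cfg.norm, rng) for s in cfg.meg_time_strides
        ]

    def forward(self, x):
        x = np.asarray(x)
        if x.ndim != 4:
            raise ValueError(
                f"expected MEG input (B, 1, sensors, samples), got shape {x.shape}"
            )
        h = self.stem(x)
        for block in self.blocks:
            h = block(h)
        return h

    def backward(self, grad):
        for block in reversed(self.blocks):
            grad = block.backward(grad)
        return self.stem.backward(grad)

    def out_shape(self, sensors: int, samples: int) -> tuple[int, int, int]:
        t = conv_out_len(samples, 15, self.cfg.meg_stem_stride[1], 7)
        s = conv_out_len(sensors, 1, self.cfg.meg_stem_stride[0], 0)
        s = conv_out_len(s, 3, 1, 1)
        t = conv_out_len(t, 3, 1, 1)
        for st in self.cfg.meg_time_strides:
            s = conv_out_len(s, 3, 1, 1)
            t = conv_out_len(t, 3, st, 1)
        return (self.cfg.base_channels, s, t)


class MRIBranch(Module):
    """3D branch with a wide 7x7x7 stem and isotropic downsampling."""

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator | None = None,
                 in_ch: int = 1):
        if rng is None:
            rng = np.random.default_rng(0)
        C = cfg.base_channels
        self.cfg = cfg
        self.stem = Sequential(
            Conv3d(in_ch, C, 7, stride=cfg.mri_stem_stride, padding=3, rng=rng),
            make_norm(cfg.norm, C),
            ReLU(),
        )
        self.blocks = [
            ResBlock(3, C, C, s, cfg.norm, rng) for s in cfg.mri_strides
        ]

    def forward(self, x):
        x = np.asarray(x)
        if x.ndim != 5:
            raise ValueError(
                f"expected MRI input (B, 1, X, Y, Z), got shape {x.shape}"
            )
        h = self.stem(x)
        for block in self.blocks:
            h = block(h)
        return h

    def backward(self, grad):
        for block in reversed(self.blocks):
            grad = block.backward(grad)
        return self.stem.backward(grad)

    def out_shape(self, *dims: int) -> tuple[int, ...]:
        out = []
        for n in dims:
            v = conv_out_len(n, 7, self.cfg.mri_stem_stride, 3)
            for st in self.cfg.mri_strides:
                v = conv_out_len(v, 3, st, 1)
            out.append(v)
        return (self.cfg.base_channels,) + tuple(out)
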