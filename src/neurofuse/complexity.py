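"""Architecture accounting: exact parameter counts and FLOPs estimates.

FLOPs follow a declared convention — 2 x multiply-accumulates for
convolution, linear and attention matmuls at their actual output shapes,
plus bias additions; normalization, activations and pooling are excluded.
Absolute FLOP figures depend on the counting convention in use, so only
ordering/ratio relations are asserted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FusionModel, ModelConfig, build_model
from .nn import FlopTape, flop_tape

CONVENTION = FlopTape.convention

FULL_MEG_SHAPE = (102, 8192)
FULL_MRI_SHAPE = (192, 192, 192)


@dataclass(frozen=True)
class ComplexityReport:
    method: str
    params: int
    flops: int
    input_size: str
    convention: str = CONVENTION

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def flops_g(self) -> float:
        return self.flops / 1e9


def count_params(model: FusionModel) -> int:
    """Sum of all learnable scalars (weights, biases, norm affine, embeddings)."""
    return model.num_params()


def count_flops(model: FusionModel, meg_shape=FULL_MEG_SHAPE,
                mri_shape=FULL_MRI_SHAPE) -> int:
    """FLOPs of one forward pass at batch 1 under the stated convention."""
    meg = np.zeros((1,) + tuple(meg_shape), dtype=np.float32)
    mri = np.zeros((1,) + tuple(mri_shape), dtype=np.float32)
    model.eval()
    with flop_tape() as tape:
        model.forward(meg, mri)
    return tape.flops


def complexity_report(cfg: ModelConfig, meg_shape=FULL_MEG_SHAPE,
                      mri_shape=FULL_MRI_SHAPE) -> ComplexityReport:
    model = build_model(cfg)
    needs_meg = cfg.strategy in ("meg_only", "early", "inter", "late")
    needs_mri = cfg.strategy in ("mri_only", "early", "inter", "late")
    parts = []
    if needs_meg:
        parts.append(f"(1,{','.join(map(str, meg_shape))})")
    if needs_mri:
        parts.append(f"(1,{','.join(map(str, mri_shape))})")
    return ComplexityReport(
        method=cfg.strategy,
        params=count_params(model),
        flops=count_flops(model, meg_shape, mri_shape),
        input_size=" & ".join(parts),
    )


def complexity_table(configs: list[ModelConfig], meg_shape=FULL_MEG_SHAPE,
                     mri_shape=FULL_MRI_SHAPE) -> pd.DataFrame:
    """One row per strategy: method, #Param (M), FLOPs (G), convention."""
    reports = [complexity_report(c, meg_shape, mri_shape) for c in configs]
    return pd.DataFrame([
        {"method": r.method, "input_size": r.input_size,
         "params": r.params, "params_M": r.params_m,
         "flops": r.flops, "flops_G": r.flops_g,
         "convention": r.convention}
        for r in reports
    ])
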