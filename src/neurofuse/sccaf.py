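"""Spatial-Channel Cross-Attention Fusion (SCCAF).

Three stages fuse the two branch feature maps:

* **MMPE** (multi-modal patch embedding) - adaptive average pooling to a
  shared token count P (64x64 = 16x16x16 = 4096 at full resolution),
  flattening to P x C token matrices, a per-channel depth-wise projection
  (scale + bias) and an optional learned positional embedding.
* **SCA** (spatial-wise cross-modal attention) - scaled dot-product attention
  where the query comes from the *other* modality and key/value from the
  same modality, so each modality's output attends over its own values under
  the other modality's queries.
* **CFA** (channel-wise feature aggregation) - the two attended outputs are
  concatenated, an MLP produces one logit pair per (token, channel), and a
  softmax over the pair yields convex weights (w_a, w_b) that mix the two
  token matrices: F_fusion = w_a * F_meg + w_b * F_mri.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Parameter, ReLU, record_flops
from .nn.core import DTYPE


@dataclass
class SCCAFConfig:
    pool_2d: tuple[int, int] = (64, 64)
    pool_3d: tuple[int, int, int] = (16, 16, 16)
    heads: int = 1
    mlp_hidden: int | None = None  # defaults to 2C
    positional_embedding: bool = True
    weight_shape: str = "per_token"  # or "per_channel"

    def __post_init__(self):
        if int(np.prod(self.pool_2d)) != int(np.prod(self.pool_3d)):
            raise ValueError(
                f"pool sizes must agree on token count: {self.pool_2d} gives "
                f"{int(np.prod(self.pool_2d))}, {self.pool_3d} gives "
                f"{int(np.prod(self.pool_3d))}"
            )
        if self.weight_shape not in ("per_token", "per_channel"):
            raise ValueError("weight_shape must be 'per_token' or 'per_channel'")

    @property
    def tokens(self) -> int:
        return int(np.prod(self.pool_2d))


def reduced_sccaf_config() -> SCCAFConfig:
    """Token grid for the reduced benchmark shapes (P = 8x8 = 4x4x4 = 64)."""
    return SCCAFConfig(pool_2d=(8, 8), pool_3d=(4, 4, 4))


# -- functional attention (dtype-preserving; the unit oracle target) --------

def scaled_cross_attention(Q, K, V, scale: float | None = None):
    """softmax(Q K^T / scale) V with row-stochastic attention weights.

    Accepts (P, C) or batched (..., P, C) arrays; ``scale`` defaults to
    sqrt(C). Computation keeps the input dtype.
    """
    Q, K, V = (np.asarray(a) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"channel mismatch: Q has {Q.shape[-1]}, K has {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must share the token count")
    if scale is None:
        scale = float(np.sqrt(Q.shape[-1]))
    S = Q @ np.swapaxes(K, -1, -2) / scale
    S = S - S.max(axis=-1, keepdims=True)
    A = np.exp(S)
    A /= A.sum(axis=-1, keepdims=True)
    return A @ V


class _Attention(Module):
    """Batched multi-head scaled dot-product attention with backward."""

    def __init__(self, channels: int, heads: int = 1):
        if channels % heads:
            raise ValueError("channels must be divisible by heads")
        self.channels = channels
        self.heads = heads
        self.d = channels // heads
        self.scale = float(np.sqrt(channels if heads == 1 else self.d))

    def _split(self, x):  # (B,P,C) -> (B,h,P,d)
        B, P, _ = x.shape
        return x.reshape(B, P, self.heads, self.d).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,h,P,d) -> (B,P,C)
        B, h, P, d = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(B, P, h * d)

    def forward(self, Q, K, V):
        Qh, Kh, Vh = self._split(Q), self._split(K), self._split(V)
        S = Qh @ np.swapaxes(Kh, -1, -2) / self.scale
        S -= S.max(axis=-1, keepdims=True)
        A = np.exp(S)
        A /= A.sum(axis=-1, keepdims=True)
        Z = A @ Vh
        B, h, Pq, _ = Qh.shape
        Pk = Kh.shape[2]
        record_flops(macs=2 * B * h * Pq * Pk * self.d)
        if self.training:
            self._cache = (A, Qh, Kh, Vh)
        return self._merge(Z)

    def backward(self, dZ):
        A, Qh, Kh, Vh = self._cache
        dZh = self._split(dZ)
        dV = np.swapaxes(A, -1, -2) @ dZh
        dA = dZh @ np.swapaxes(Vh, -1, -2)
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = dS @ Kh / self.scale
        dK = np.swapaxes(dS, -1, -2) @ Qh / self.scale
        return self._merge(dQ), self._merge(dK), self._merge(dV)

    @property
    def last_attention(self):
        """Attention weights of the most recent training-mode forward."""
        return self._cache[0]


class MMPE(Module):
    """Pool a branch feature map to the token grid and embed it."""

    def __init__(self, channels: int, pool_size, positional_embedding: bool = True,
                 rng: np.random.Generator | None = None):
        from .nn import AdaptiveAvgPool

        if rng is None:
            rng = np.random.default_rng(0)
        self.pool_size = tuple(int(s) for s in pool_size)
        self.channels = channels
        self.pool = AdaptiveAvgPool(self.pool_size)
        self.scale = Parameter(np.ones(channels))
        self.shift = Parameter(np.zeros(channels))
        P = int(np.prod(self.pool_size))
        self.pos = (
            Parameter(rng.normal(0.0, 0.02, size=(P, channels)))
            if positional_embedding else None
        )

    def forward(self, f):
        f = np.asarray(f, dtype=DTYPE)
        if f.ndim != len(self.pool_size) + 2:
            raise ValueError(
                f"feature map rank {f.ndim} does not match pool {self.pool_size}"
            )
        pooled = self.pool(f)  # (B, C, *pool)
        B, C = pooled.shape[:2]
        P = int(np.prod(self.pool_size))
        tok = np.ascontiguousarray(pooled.reshape(B, C, P).transpose(0, 2, 1))
        out = tok * self.scale.data + self.shift.data
        record_flops(macs=B * P * C)
        if self.pos is not None:
            out = out + self.pos.data
        if self.training:
            self._cache = (tok, (B, C) + self.pool_size)
        return out

    def backward(self, grad):
        tok, pooled_shape = self._cache
        if self.pos is not None:
            self.pos.grad += grad.sum(axis=0)
        self.scale.grad += (grad * tok).sum(axis=(0, 1))
        self.shift.grad += grad.sum(axis=(0, 1))
        dtok = grad * self.scale.data
        B, C = pooled_shape[:2]
        dpooled = np.ascontiguousarray(dtok.transpose(0, 2, 1)).reshape(pooled_shape)
        return self.pool.backward(dpooled)


class SCA(Module):
    """Cross-modal attention; queries swap modality, key/value stay home."""

    def __init__(self, channels: int, heads: int = 1,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        mk = lambda: Linear(channels, channels, bias=False, rng=rng)
        self.q_meg, self.k_meg, self.v_meg = mk(), mk(), mk()
        self.q_mri, self.k_mri, self.v_mri = mk(), mk(), mk()
        self.attn_a = _Attention(channels, heads)  # output valued in MEG
        self.attn_b = _Attention(channels, heads)  # output valued in MRI

    def forward(self, tok_meg, tok_mri):
        if tok_meg.shape != tok_mri.shape:
            raise ValueError(
                f"token matrices must match: {tok_meg.shape} vs {tok_mri.shape}"
            )
        Z_a = self.attn_a(self.q_mri(tok_mri), self.k_meg(tok_meg),
                          self.v_meg(tok_meg))
        Z_b = self.attn_b(self.q_meg(tok_meg), self.k_mri(tok_mri),
                          self.v_mri(tok_mri))
        return Z_a, Z_b

    def backward(self, dZ_a, dZ_b):
        dQa, dKa, dVa = self.attn_a.backward(dZ_a)
        dQb, dKb, dVb = self.attn_b.backward(dZ_b)
        dmeg = (self.k_meg.backward(dKa) + self.v_meg.backward(dVa)
                + self.q_meg.backward(dQb))
        dmri = (self.q_mri.backward(dQa) + self.k_mri.backward(dKb)
                + self.v_mri.backward(dVb))
        return dmeg, dmri


class CFA(Module):
    """Softmax-weighted convex mixing of the two modalities' tokens."""

    def __init__(self, channels: int, hidden: int | None = None,
                 weight_shape: str = "per_token",
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        if hidden is None:
            hidden = 2 * channels
        self.channels = channels
        self.weight_shape = weight_shape
        self.fc1 = Linear(2 * channels, hidden, rng=rng)
        self.act = ReLU()
        self.fc2 = Linear(hidden, 2 * channels, rng=rng)

    def _logits_to_weights(self, logits):
        B, P = logits.shape[:2]
        l = logits.reshape(B, P, self.channels, 2)
        if self.weight_shape == "per_channel":
            l = l.mean(axis=1, keepdims=True)
        l = l - l.max(axis=-1, keepdims=True)
        w = np.exp(l)
        w /= w.sum(axis=-1, keepdims=True)
        return w  # (B, P or 1, C, 2)

    def forward(self, Z_a, Z_b, tok_meg, tok_mri):
        F_c = np.concatenate([Z_a, Z_b], axis=-1)
        logits = self.fc2(self.act(self.fc1(F_c)))
        w = self._logits_to_weights(logits)
        out = w[..., 0] * tok_meg + w[..., 1] * tok_mri
        if self.training:
            self._cache = (w, tok_meg, tok_mri, Z_a.shape)
        return out

    def weights(self, Z_a, Z_b):
        """(w_a, w_b) for given attended features; rows of a 2-simplex."""
        F_c = np.concatenate([Z_a, Z_b], axis=-1)
        w = self._logits_to_weights(self.fc2(self.act(self.fc1(F_c))))
        return w[..., 0], w[..., 1]

    def backward(self, dout):
        w, tok_meg, tok_mri, z_shape = self._cache
        dtok_meg = dout * w[..., 0]
        dtok_mri = dout * w[..., 1]
        dw = np.stack([dout * tok_meg, dout * tok_mri], axis=-1)
        if self.weight_shape == "per_channel":
            dw = dw.sum(axis=1, keepdims=True)
        dlogits = w * (dw - (dw * w).sum(axis=-1, keepdims=True))
        B, P = z_shape[:2]
        if self.weight_shape == "per_channel":
            dlogits = np.broadcast_to(dlogits / P, (B, P, self.channels, 2)).copy()
        dlogits = dlogits.reshape(B, P, 2 * self.channels)
        dF = self.fc1.backward(self.act.backward(self.fc2.backward(dlogits)))
        dZ_a, dZ_b = dF[..., : self.channels], dF[..., self.channels:]
        return dZ_a, dZ_b, dtok_meg, dtok_mri


class SCCAFModule(Module):
    """MMPE -> SCA -> CFA over the two branch feature maps."""

    def __init__(self, channels: int, cfg: SCCAFConfig | None = None,
                 rng: np.random.Generator | None = None):
        if cfg is None:
            cfg = SCCAFConfig()
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        self.channels = channels
        self.mmpe_meg = MMPE(channels, cfg.pool_2d, cfg.positional_embedding, rng)
        self.mmpe_mri = MMPE(channels, cfg.pool_3d, cfg.positional_embedding, rng)
        self.sca = SCA(channels, cfg.heads, rng)
        self.cfa = CFA(channels, cfg.mlp_hidden, cfg.weight_shape, rng)

    def forward(self, f_meg, f_mri):
        tok_meg = self.mmpe_meg(f_meg)
        tok_mri = self.mmpe_mri(f_mri)
        Z_a, Z_b = self.sca(tok_meg, tok_mri)
        return self.cfa(Z_a, Z_b, tok_meg, tok_mri)

    def backward(self, dfused):
        dZ_a, dZ_b, dtok_meg, dtok_mri = self.cfa.backward(dfused)
        dmeg_sca, dmri_sca = self.sca.backward(dZ_a, dZ_b)
        df_meg = self.mmpe_meg.backward(dtok_meg + dmeg_sca)
        df_mri = self.mmpe_mri.backward(dtok_mri + dmri_sca)
        return df_meg, df_mri
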