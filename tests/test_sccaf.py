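"""SCCAF fusion: token contracts, attention oracles, simplex invariants."""

import numpy as np
import pytest

from neurofuse.nn.core import DTYPE
from neurofuse.sccaf import (
    CFA, MMPE, SCA, SCCAFConfig, SCCAFModule, scaled_cross_attention,
)


def brute_force_attention(Q, K, V, scale):
    """Row-by-row softmax-weighted sum, written independently of the library."""
    out = np.zeros((Q.shape[0], V.shape[1]))
    for i in range(Q.shape[0]):
        logits = np.array([Q[i] @ K[j] / scale for j in range(K.shape[0])])
        weights = np.exp(logits - logits.max())
        weights /= weights.sum()
        out[i] = sum(w * V[j] for j, w in enumerate(weights))
    return out


class TestScaledCrossAttention:
    def test_single_key_value_token_returns_value(self, rng):
        Q = rng.standard_normal((5, 3))
        K = rng.standard_normal((1, 3))
        V = rng.standard_normal((1, 3))
        out = scaled_cross_attention(Q, K, V)
        assert np.allclose(out, np.repeat(V, 5, axis=0), atol=1e-12)

    def test_identical_keys_give_uniform_attention(self, rng):
        Q = rng.standard_normal((4, 3))
        K = np.repeat(rng.standard_normal((1, 3)), 6, axis=0)
        V = rng.standard_normal((6, 3))
        out = scaled_cross_attention(Q, K, V)
        assert np.allclose(out, np.repeat(V.mean(axis=0)[None], 4, axis=0),
                           atol=1e-12)

    def test_matches_brute_force_oracle_on_small_token_sets(self, rng):
        for trial in range(10):
            P, C = rng.integers(2, 9), rng.integers(2, 5)
            Q = rng.standard_normal((P, C))
            K = rng.standard_normal((P, C))
            V = rng.standard_normal((P, C))
            out = scaled_cross_attention(Q, K, V)
            expected = brute_force_attention(Q, K, V, np.sqrt(C))
            assert np.abs(out - expected).max() <= 1e-6

    def test_hand_enumerable_two_token_case(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = np.array([[1.0, 1.0], [0.0, -1.0]])
        V = np.array([[2.0, 0.0], [0.0, 2.0]])
        out = scaled_cross_attention(Q, K, V)
        expected = brute_force_attention(Q, K, V, np.sqrt(2))
        assert np.abs(out - expected).max() <= 1e-6

    def test_permuting_key_value_rows_together_is_invariant(self, rng):
        Q = rng.standard_normal((6, 4))
        K = rng.standard_normal((8, 4))
        V = rng.standard_normal((8, 4))
        perm = rng.permutation(8)
        assert np.allclose(scaled_cross_attention(Q, K, V),
                           scaled_cross_attention(Q, K[perm], V[perm]),
                           atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            scaled_cross_attention(rng.standard_normal((3, 4)),
                                   rng.standard_normal((3, 5)),
                                   rng.standard_normal((3, 5)))

    def test_attention_rows_sum_to_one(self, rng):
        from neurofuse.sccaf import _Attention

        attn = _Attention(channels=4, heads=1)
        attn.train()
        attn(rng.standard_normal((2, 5, 4)).astype(DTYPE) * 10,
             rng.standard_normal((2, 5, 4)).astype(DTYPE) * 10,
             rng.standard_normal((2, 5, 4)).astype(DTYPE))
        A = attn.last_attention
        assert np.abs(A.sum(axis=-1) - 1.0).max() < 1e-6


class TestMMPE:
    def test_default_pools_give_4096_tokens_for_both_modalities(self):
        cfg = SCCAFConfig()
        assert cfg.tokens == 4096
        meg = MMPE(2, cfg.pool_2d)
        mri = MMPE(2, cfg.pool_3d)
        meg.eval(), mri.eval()
        tok2 = meg(np.zeros((1, 2, 102, 128), dtype=DTYPE))
        tok3 = mri(np.zeros((1, 2, 24, 24, 24), dtype=DTYPE))
        assert tok2.shape == (1, 4096, 2)
        assert tok3.shape == (1, 4096, 2)

    def test_constant_map_gives_identical_token_rows(self):
        mmpe = MMPE(3, (4, 4), positional_embedding=False)
        mmpe.eval()
        f = np.full((1, 3, 9, 13), 2.5, dtype=DTYPE)
        tok = mmpe(f)
        assert np.allclose(tok, tok[:, :1, :], atol=1e-6)

    def test_pooling_matches_window_mean_oracle(self, rng):
        mmpe = MMPE(1, (2, 2), positional_embedding=False)
        mmpe.eval()
        f = rng.standard_normal((1, 1, 4, 4)).astype(DTYPE)
        tok = mmpe(f).reshape(2, 2)
        expected = np.array([
            [f[0, 0, :2, :2].mean(), f[0, 0, :2, 2:].mean()],
            [f[0, 0, 2:, :2].mean(), f[0, 0, 2:, 2:].mean()],
        ])
        assert np.allclose(tok, expected, atol=1e-6)

    def test_pool_larger_than_input_rejected(self):
        mmpe = MMPE(1, (8, 8))
        with pytest.raises(ValueError):
            mmpe(np.zeros((1, 1, 4, 4), dtype=DTYPE))

    def test_mismatched_pool_sizes_rejected(self):
        with pytest.raises(ValueError, match="token count"):
            SCCAFConfig(pool_2d=(8, 8), pool_3d=(4, 4, 5))


class TestSCA:
    def _tied_identity(self, sca):
        for lin in (sca.q_meg, sca.k_meg, sca.v_meg,
                    sca.q_mri, sca.k_mri, sca.v_mri):
            lin.weight.data[...] = np.eye(lin.weight.data.shape[0])

    def test_identical_inputs_and_tied_maps_give_equal_outputs(self, rng):
        sca = SCA(4, rng=np.random.default_rng(0))
        self._tied_identity(sca)
        sca.eval()
        tok = rng.standard_normal((1, 6, 4)).astype(DTYPE)
        Z_a, Z_b = sca(tok, tok.copy())
        assert np.allclose(Z_a, Z_b, atol=1e-6)

    def test_outputs_inside_convex_hull_of_values(self, rng):
        sca = SCA(4, rng=np.random.default_rng(1))
        self._tied_identity(sca)
        sca.eval()
        tok_meg = rng.standard_normal((1, 8, 4)).astype(DTYPE)
        tok_mri = rng.standard_normal((1, 8, 4)).astype(DTYPE)
        Z_a, Z_b = sca(tok_meg, tok_mri)
        # with identity V maps, values are the raw tokens of the home modality
        for Z, V in [(Z_a, tok_meg), (Z_b, tok_mri)]:
            assert (Z[0] <= V[0].max(axis=0) + 1e-5).all()
            assert (Z[0] >= V[0].min(axis=0) - 1e-5).all()

    def test_identity_maps_match_functional_composition(self, rng):
        sca = SCA(4, rng=np.random.default_rng(2))
        self._tied_identity(sca)
        sca.eval()
        tok_meg = rng.standard_normal((1, 8, 4)).astype(DTYPE)
        tok_mri = rng.standard_normal((1, 8, 4)).astype(DTYPE)
        Z_a, Z_b = sca(tok_meg, tok_mri)
        exp_a = scaled_cross_attention(tok_mri[0], tok_meg[0], tok_meg[0])
        exp_b = scaled_cross_attention(tok_meg[0], tok_mri[0], tok_mri[0])
        assert np.abs(Z_a[0] - exp_a).max() < 1e-5
        assert np.abs(Z_b[0] - exp_b).max() < 1e-5

    def test_shape_mismatch_rejected(self, rng):
        sca = SCA(4)
        with pytest.raises(ValueError):
            sca(np.zeros((1, 8, 4), dtype=DTYPE), np.zeros((1, 6, 4), dtype=DTYPE))


class TestCFA:
    def test_equal_logits_give_half_half_mixture(self, rng):
        cfa = CFA(3, rng=np.random.default_rng(0))
        cfa.fc2.weight.data[...] = 0.0
        cfa.fc2.bias.data[...] = 0.0
        cfa.eval()
        tok_meg = rng.standard_normal((1, 5, 3)).astype(DTYPE)
        tok_mri = rng.standard_normal((1, 5, 3)).astype(DTYPE)
        Z = rng.standard_normal((1, 5, 3)).astype(DTYPE)
        out = cfa(Z, Z, tok_meg, tok_mri)
        assert np.allclose(out, 0.5 * (tok_meg + tok_mri), atol=1e-6)

    def test_saturated_logits_select_one_modality(self, rng):
        cfa = CFA(3, rng=np.random.default_rng(0))
        cfa.fc2.weight.data[...] = 0.0
        bias = cfa.fc2.bias.data.reshape(3, 2)
        bias[:, 0] = 20.0   # logit for the MEG weight
        bias[:, 1] = -20.0
        cfa.eval()
        tok_meg = rng.standard_normal((1, 5, 3)).astype(DTYPE)
        tok_mri = rng.standard_normal((1, 5, 3)).astype(DTYPE)
        Z = rng.standard_normal((1, 5, 3)).astype(DTYPE)
        out = cfa(Z, Z, tok_meg, tok_mri)
        assert np.abs(out - tok_meg).max() < 1e-4

    @pytest.mark.parametrize("weight_shape", ["per_token", "per_channel"])
    def test_weights_on_simplex_and_output_is_weighted_sum(self, rng, weight_shape):
        cfa = CFA(4, weight_shape=weight_shape, rng=np.random.default_rng(3))
        cfa.eval()
        tok_meg = rng.standard_normal((2, 6, 4)).astype(DTYPE)
        tok_mri = rng.standard_normal((2, 6, 4)).astype(DTYPE)
        Z_a = rng.standard_normal((2, 6, 4)).astype(DTYPE)
        Z_b = rng.standard_normal((2, 6, 4)).astype(DTYPE)
        w_a, w_b = cfa.weights(Z_a, Z_b)
        assert np.abs(w_a + w_b - 1.0).max() <= 1e-6
        assert (w_a > 0).all() and (w_a < 1).all()
        out = cfa(Z_a, Z_b, tok_meg, tok_mri)
        assert np.allclose(out, w_a * tok_meg + w_b * tok_mri, atol=1e-6)


class TestSCCAFModule:
    def test_gradients_reach_both_branch_inputs(self, rng):
        cfg = SCCAFConfig(pool_2d=(2, 2), pool_3d=(2, 2, 1))
        mod = SCCAFModule(3, cfg, np.random.default_rng(0))
        mod.train()
        f_meg = rng.standard_normal((2, 3, 4, 6)).astype(DTYPE)
        f_mri = rng.standard_normal((2, 3, 4, 4, 2)).astype(DTYPE)
        fused = mod(f_meg, f_mri)
        df_meg, df_mri = mod.backward(np.ones_like(fused))
        for g in (df_meg, df_mri):
            assert np.all(np.isfinite(g))
            assert np.abs(g).max() > 0

    def test_fused_output_shape(self, rng):
        cfg = SCCAFConfig(pool_2d=(4, 4), pool_3d=(4, 2, 2))
        mod = SCCAFModule(5, cfg, np.random.default_rng(0))
        mod.eval()
        out = mod(rng.standard_normal((1, 5, 8, 8)).astype(DTYPE),
                  rng.standard_normal((1, 5, 8, 8, 4)).astype(DTYPE))
        assert out.shape == (1, 16, 5)
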