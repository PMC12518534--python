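"""Channel-attention operators: cross-covariance attention, top-k
sparsification, the sparse multi-branch operator, Mix-FFN, and the full
dual-attention block."""

import numpy as np
import pytest
from fractions import Fraction
from hypothesis import given, settings, strategies as st

import dcfnet.autodiff as ad
from dcfnet import nn
from dcfnet.attention import (CasaBlock, MixFFN, casa_block, mix_ffn,
                              round_half_up, tksa_attention, topk_mask,
                              xca_attention)
from dcfnet.autodiff import as_tensor
from dcfnet.config import CasaConfig, ConfigError


def dense_xca_oracle(Q, K, V, tau):
    """Literal-formula reference: explicit d x d cross-covariance."""
    Qn = Q / np.linalg.norm(Q, axis=0, keepdims=True)
    Kn = K / np.linalg.norm(K, axis=0, keepdims=True)
    S = Kn.T @ Qn / tau
    E = np.exp(S - S.max(axis=0, keepdims=True))
    return V @ (E / E.sum(axis=0, keepdims=True))


class TestXCA:
    def test_single_channel_is_identity(self, rng):
        Q, K, V = rng.normal(size=(3, 6, 1))
        np.testing.assert_allclose(xca_attention(Q, K, V, 1.0), V)

    def test_matches_dense_matrix_oracle(self, rng):
        Q, K, V = rng.normal(size=(3, 6, 3))
        np.testing.assert_allclose(xca_attention(Q, K, V, 0.7),
                                   dense_xca_oracle(Q, K, V, 0.7), atol=1e-12)

    def test_presoftmax_entries_lie_in_open_unit_interval(self, rng):
        # l2-normalized columns force every cross-covariance entry into (-1, 1)
        from dcfnet.attention import l2_normalize_channels
        for _ in range(20):
            Q, K = rng.normal(size=(2, 30, 6))
            Qn = l2_normalize_channels(as_tensor(Q)).data
            Kn = l2_normalize_channels(as_tensor(K)).data
            S = Kn.T @ Qn
            assert np.all(S > -1.0) and np.all(S < 1.0)

    def test_attention_weights_sum_to_one_per_output_channel(self, rng):
        Q, K, V = rng.normal(size=(3, 6, 3))
        Qn = Q / np.linalg.norm(Q, axis=0, keepdims=True)
        Kn = K / np.linalg.norm(K, axis=0, keepdims=True)
        S = Kn.T @ Qn / 0.5
        E = np.exp(S - S.max(axis=0, keepdims=True))
        A = E / E.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(A.sum(axis=0), np.ones(3), atol=1e-6)
        # and the operator output is V @ A for exactly that A
        np.testing.assert_allclose(xca_attention(Q, K, V, 0.5), V @ A, atol=1e-12)

    def test_rejects_bad_inputs(self, rng):
        Q = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            xca_attention(Q, Q[:, :2], Q, 1.0)
        with pytest.raises(ConfigError):
            xca_attention(Q, Q, Q, tau=0.0)


def sort_oracle_mask(S, k):
    """Brute-force reference: full sort per row, keep >= k-th largest."""
    out = np.full_like(S, -np.inf)
    for i in range(S.shape[0]):
        thr = np.sort(S[i])[::-1][k - 1]
        keep = S[i] >= thr
        out[i, keep] = S[i, keep]
    return out


class TestTopkMask:
    def test_worked_example(self):
        S = np.array([[3.0, 1.0, 2.0], [0.0, 5.0, 4.0]])
        expected = np.array([[3.0, -np.inf, 2.0], [-np.inf, 5.0, 4.0]])
        np.testing.assert_array_equal(topk_mask(S, 2), expected)

    def test_full_k_keeps_everything(self, rng):
        S = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(topk_mask(S, 5), S)

    def test_all_ties_kept(self):
        S = np.full((3, 4), 2.5)
        np.testing.assert_array_equal(topk_mask(S, 1), S)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            topk_mask(np.zeros((2, 3)), 4)

    def test_equivalence_with_sort_oracle_on_1000_random_matrices(self, rng):
        for _ in range(1000):
            rows = int(rng.integers(1, 17))
            cols = int(rng.integers(1, 17))
            S = rng.normal(size=(rows, cols))
            k = int(rng.integers(1, cols + 1))
            np.testing.assert_array_equal(topk_mask(S, k), sort_oracle_mask(S, k))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_kept_count_and_threshold_property(self, data):
        rows = data.draw(st.integers(1, 8))
        cols = data.draw(st.integers(1, 12))
        k = data.draw(st.integers(1, cols))
        S = np.array(data.draw(st.lists(
            st.lists(st.integers(-5, 5), min_size=cols, max_size=cols),
            min_size=rows, max_size=rows)), dtype=float)
        M = topk_mask(S, k)
        for i in range(rows):
            kept = np.isfinite(M[i])
            assert kept.sum() >= k  # ties can only add entries
            if kept.sum() < cols:
                assert S[i][kept].min() > S[i][~kept].max()


class TestTKSA:
    def test_full_density_single_branch_equals_dense_transposed_attention(self, rng):
        X = rng.normal(size=(10, 8))
        cfg = CasaConfig(num_heads=2, k_fractions=(Fraction(1, 1),))
        out = tksa_attention(X, cfg, tau=1.3)
        ref = np.zeros_like(X)
        for h in range(2):
            Xc = X[:, 4 * h:4 * (h + 1)].T        # channel-major (ch, N)
            S = (Xc @ Xc.T) * 1.3
            E = np.exp(S - S.max(axis=1, keepdims=True))
            A = E / E.sum(axis=1, keepdims=True)
            ref[:, 4 * h:4 * (h + 1)] = (A @ Xc).T
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_default_fractions_round_to_expected_k(self):
        ks = [round_half_up(float(f) * 20)
              for f in CasaConfig().k_fractions]
        assert ks == [10, 13, 15, 16]  # C_head = 20

    def test_masked_softmax_rows_sum_to_one(self, rng):
        X = rng.normal(size=(2, 12, 16))
        cfg = CasaConfig(num_heads=4)
        Xc = X.reshape(2, 12, 4, 4).transpose(0, 2, 3, 1)
        S = Xc @ np.swapaxes(Xc, -1, -2)
        M = topk_mask(S.reshape(-1, 4), 2).reshape(S.shape)
        E = np.where(np.isfinite(M), np.exp(M - M.max(axis=-1, keepdims=True)), 0.0)
        A = E / E.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-6)

    def test_branch_weights_scale_linearly(self, rng):
        X = rng.normal(size=(6, 4))
        cfg = CasaConfig(num_heads=1, k_fractions=(Fraction(1, 2), Fraction(1, 1)))
        base = tksa_attention(X, cfg, alphas=[1.0, 1.0])
        doubled = tksa_attention(X, cfg, alphas=[2.0, 2.0])
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-10)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ConfigError):
            tksa_attention(rng.normal(size=(5, 6)), CasaConfig(num_heads=4))


class TestMixFFN:
    def test_preserves_shape(self, rng, small_casa_cfg):
        X = rng.normal(size=(12, 8))
        out = mix_ffn(X, (3, 4), small_casa_cfg)
        assert out.shape == X.shape

    def test_zeroed_weights_give_zero_output(self, rng, small_casa_cfg):
        mod = MixFFN(8, small_casa_cfg)
        for p in mod.parameters():
            p.data[:] = 0.0
        out = mix_ffn(rng.normal(size=(6, 8)), (2, 3), small_casa_cfg, module=mod)
        np.testing.assert_array_equal(out, np.zeros((6, 8)))

    def test_single_pixel_closed_form(self, rng, small_casa_cfg):
        # on a 1x1 grid the depthwise conv keeps only its center tap
        mod = MixFFN(4, small_casa_cfg)
        x = rng.normal(size=(1, 4))
        out = mix_ffn(x, (1, 1), small_casa_cfg, module=mod)
        h = x @ mod.fc1.weight.data + mod.fc1.bias.data
        dw_c = mod.dw.weight.data[:, 0, 1, 1]
        h2 = h * dw_c + mod.dw.bias.data + h
        mu, var = h2.mean(), h2.var()
        hn = (h2 - mu) / np.sqrt(var + 1e-6) * mod.norm.weight.data + mod.norm.bias.data
        from scipy.special import erf
        act = hn * 0.5 * (1 + erf(hn / np.sqrt(2)))
        ref = act @ mod.fc2.weight.data + mod.fc2.bias.data
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_token_grid_mismatch_rejected(self, rng, small_casa_cfg):
        with pytest.raises(ValueError):
            mix_ffn(rng.normal(size=(6, 8)), (2, 4), small_casa_cfg)


def zero_residual_weights(block: CasaBlock):
    for sub in ("xca", "tksa"):
        if hasattr(block, sub):
            m = getattr(block, sub)
            m.proj.weight.data[:] = 0.0
            m.proj.bias.data[:] = 0.0
    for sub in ("ffn1", "ffn2"):
        if hasattr(block, sub):
            m = getattr(block, sub)
            m.fc2.weight.data[:] = 0.0
            m.fc2.bias.data[:] = 0.0


class TestCasaBlock:
    @pytest.mark.parametrize("order", ["channel_pre", "sparse_pre", "parallel",
                                       "channel_only", "sparse_only"])
    def test_zeroed_residuals_give_identity_and_shape_is_preserved(
            self, order, rng, small_casa_cfg):
        block = CasaBlock(8, small_casa_cfg, order=order)
        x = rng.normal(size=(2, 8, 4, 4))
        assert casa_block(x, small_casa_cfg, module=block).shape == x.shape
        zero_residual_weights(block)
        np.testing.assert_allclose(casa_block(x, small_casa_cfg, module=block),
                                   x, atol=1e-12)

    def test_order_variants_differ_with_shared_weights(self, rng, small_casa_cfg):
        nn.manual_seed(0)
        a = CasaBlock(8, small_casa_cfg, order="channel_pre")
        nn.manual_seed(0)
        b = CasaBlock(8, small_casa_cfg, order="sparse_pre")
        x = rng.normal(size=(1, 8, 4, 4))
        ya = casa_block(x, small_casa_cfg, module=a)
        yb = casa_block(x, small_casa_cfg, module=b)
        assert not np.allclose(ya, yb)

    def test_gradient_reaches_every_parameter(self, rng, small_casa_cfg):
        block = CasaBlock(8, small_casa_cfg)
        x = as_tensor(rng.normal(size=(2, 8, 8, 8)))
        out = block(x)
        (out * out).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, name
            norm = np.linalg.norm(p.grad)
            assert np.isfinite(norm) and norm > 0, name

    def test_rejects_nonfinite_input(self, small_casa_cfg):
        x = np.full((1, 8, 2, 2), np.nan)
        with pytest.raises(ValueError):
            casa_block(x, small_casa_cfg)
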