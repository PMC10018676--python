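"""Neighborhood attention: window geometry, oracle equivalence, locality."""

import numpy as np
import pytest

from natseg.autodiff import Tensor
from natseg.errors import InvalidConfigError
from natseg.na import (AttentionConfig, MultiHeadNeighborhoodAttention,
                       full_self_attention_oracle, multi_head_neighborhood_attention,
                       na_loop_oracle, na_operation_count, neighborhood_indices)


def _module(cfg, seed=0, **kw):
    return MultiHeadNeighborhoodAttention(cfg, np.random.default_rng(seed), **kw)


class TestNeighborhoodIndices:
    def test_interior_pixel_symmetric_window(self):
        assert neighborhood_indices(2, 2, 3, 5, 5) == [
            (r, c) for r in (1, 2, 3) for c in (1, 2, 3)]

    def test_corner_window_shifts_inward(self):
        assert neighborhood_indices(0, 0, 3, 5, 5) == [
            (r, c) for r in (0, 1, 2) for c in (0, 1, 2)]
        assert neighborhood_indices(4, 4, 3, 5, 5) == [
            (r, c) for r in (2, 3, 4) for c in (2, 3, 4)]

    def test_every_window_has_s_squared_inbounds_pixels(self):
        for i in range(6):
            for j in range(6):
                win = neighborhood_indices(i, j, 3, 6, 6)
                assert len(win) == 9
                assert len(set(win)) == 9
                assert all(0 <= r < 6 and 0 <= c < 6 for r, c in win)
                assert (i, j) in win

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(InvalidConfigError):
            neighborhood_indices(0, 0, 7, 5, 5)


class TestAttentionConfig:
    @pytest.mark.parametrize("kw", [
        dict(embed_dim=6, num_heads=4, neighborhood_size=3),
        dict(embed_dim=8, num_heads=2, neighborhood_size=4),
        dict(embed_dim=8, num_heads=2, neighborhood_size=3, scale=-1.0),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(InvalidConfigError):
            AttentionConfig(**kw)

    def test_default_scale_is_sqrt_head_dim(self):
        assert AttentionConfig(8, 2, 3).effective_scale == pytest.approx(2.0)


class TestOracleEquivalence:
    def test_vectorized_matches_per_pixel_loop_on_random_instances(self, rng):
        for trial in range(12):
            H, W = rng.integers(3, 9, size=2)
            heads = int(rng.choice([1, 2, 4]))
            C = heads * int(rng.integers(1, 5))
            S = int(rng.choice([1, 3, 5]))
            if S > min(H, W):
                S = 1
            cfg = AttentionConfig(C, heads, S)
            mod = _module(cfg, seed=trial)
            x = rng.standard_normal((int(rng.integers(1, 3)), C, H, W)).astype(np.float32)
            out = mod(Tensor(x)).data
            ref = na_loop_oracle(x, cfg, mod.export_params())
            np.testing.assert_allclose(out, ref, rtol=1e-5, atol=1e-5)

    def test_full_window_equals_dense_self_attention(self, rng):
        cfg = AttentionConfig(8, 2, 7)
        mod = _module(cfg, seed=3)
        x = rng.standard_normal((2, 8, 7, 7)).astype(np.float32)
        out = mod(Tensor(x)).data
        ref = full_self_attention_oracle(x, cfg, mod.export_params())
        np.testing.assert_allclose(out, ref, rtol=1e-5, atol=1e-5)

    def test_functional_wrapper_matches_module(self, rng):
        cfg = AttentionConfig(4, 2, 3)
        mod = _module(cfg, seed=9)
        x = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
        np.testing.assert_array_equal(
            multi_head_neighborhood_attention(x, cfg, mod.export_params()),
            mod(Tensor(x)).data)


class TestBehaviour:
    def test_single_pixel_window_is_pixelwise_value_projection(self, rng):
        cfg = AttentionConfig(6, 2, 1)
        mod = _module(cfg, seed=1)
        x = rng.standard_normal((1, 6, 4, 4)).astype(np.float32)
        out = mod(Tensor(x)).data
        p = mod.export_params()
        tok = x.transpose(0, 2, 3, 1).reshape(1, 16, 6)
        expected = ((tok @ p["wv"] + p["bv"]) @ p["wo"] + p["bo"])
        expected = expected.reshape(1, 4, 4, 6).transpose(0, 3, 1, 2)
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-6)

    def test_attention_weights_are_a_distribution(self, rng):
        cfg = AttentionConfig(8, 4, 3)
        mod = _module(cfg, seed=2)
        x = rng.standard_normal((2, 8, 6, 5)).astype(np.float32)
        _, weights = mod(Tensor(x), return_weights=True)
        assert (weights >= 0).all()
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_locality_out_of_window_pixels_do_not_leak(self, rng):
        # pre-projection NA output at (0, 0) depends only on its clamped window
        cfg = AttentionConfig(4, 1, 3)
        mod = _module(cfg, seed=5)
        x = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        y = x.copy()
        y[:, :, 7, 7] += 5.0   # far outside the (0,0) window {0,1,2}x{0,1,2}
        out_x = mod(Tensor(x)).data
        out_y = mod(Tensor(y)).data
        np.testing.assert_allclose(out_x[:, :, 0, 0], out_y[:, :, 0, 0], atol=1e-6)
        assert not np.allclose(out_x[:, :, 7, 7], out_y[:, :, 7, 7], atol=1e-3)

    def test_dense_attention_is_permutation_equivariant_without_bias(self, rng):
        cfg = AttentionConfig(4, 2, 3)
        mod = _module(cfg, seed=6)
        params = mod.export_params()
        params["bias"] = np.zeros_like(params["bias"])
        x = rng.standard_normal((1, 4, 1, 9))   # 1-row image: any column permutation
        perm = rng.permutation(9)
        out = full_self_attention_oracle(x, cfg, params)
        out_p = full_self_attention_oracle(x[:, :, :, perm], cfg, params)
        np.testing.assert_allclose(out_p, out[:, :, :, perm], rtol=1e-8, atol=1e-10)

    def test_single_pixel_dense_oracle_is_value_path(self, rng):
        cfg = AttentionConfig(4, 1, 1)
        mod = _module(cfg, seed=7)
        p = mod.export_params()
        x = rng.standard_normal((1, 4, 1, 1))
        out = full_self_attention_oracle(x, cfg, p)
        expected = ((x.reshape(1, 4) @ p["wv"] + p["bv"]) @ p["wo"] + p["bo"]).reshape(1, 4, 1, 1)
        np.testing.assert_allclose(out, expected, rtol=1e-6)

    def test_window_exceeding_image_rejected_unless_auto_shrink(self, rng):
        cfg = AttentionConfig(4, 1, 7)
        x = Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
        with pytest.raises(InvalidConfigError):
            _module(cfg)(x)
        out = _module(cfg, auto_shrink=True)(x)
        assert out.shape == (1, 4, 5, 5)

    def test_non_finite_input_rejected(self):
        cfg = AttentionConfig(4, 1, 3)
        x = np.zeros((1, 4, 4, 4), dtype=np.float32)
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            _module(cfg)(Tensor(x))

    def test_operation_count_scales_linearly_in_pixels(self):
        base = na_operation_count(16, 16, 7, 32, 4)
        assert na_operation_count(32, 16, 7, 32, 4) == 2 * base
        assert na_operation_count(32, 32, 7, 32, 4) == 4 * base
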