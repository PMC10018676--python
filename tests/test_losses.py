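"""Loss components: closed-form reductions, hand-computed values, gradients."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from natseg.autodiff import Tensor
from natseg.errors import InvalidConfigError, ShapeError
from natseg.losses import (FocalConfig, LossWeights, MixedLossConfig, MsSsimConfig,
                           TverskyConfig, focal_loss, mixed_loss, ms_ssim_loss,
                           one_hot, tversky_loss)

from conftest import numerical_grad


class TestMsSsim:
    def test_identical_maps_have_zero_loss(self, rng):
        p = rng.random((48, 48))
        assert float(ms_ssim_loss(p, p.copy(), MsSsimConfig(num_scales=2)).data) == \
            pytest.approx(0.0, abs=1e-9)

    def test_inverted_checkerboard_scores_worse_than_identity(self):
        t = np.indices((64, 64)).sum(axis=0) % 2
        t = t.astype(float)
        cfg = MsSsimConfig(num_scales=1)
        loss_same = float(ms_ssim_loss(t, t, cfg).data)
        loss_anti = float(ms_ssim_loss(1.0 - t, t, cfg).data)
        assert loss_anti > loss_same

    def test_single_scale_matches_reference_ssim(self, rng):
        p = rng.random((32, 32))
        t = rng.random((32, 32))
        cfg = MsSsimConfig(num_scales=1, window_size=11)
        ours = 1.0 - float(ms_ssim_loss(p, t, cfg).data)
        ref = structural_similarity(
            t, p, win_size=11, data_range=1.0, gaussian_weights=False,
            use_sample_covariance=False)
        assert ours == pytest.approx(ref, abs=1e-5)

    def test_too_many_scales_error_names_feasible_maximum(self):
        with pytest.raises(InvalidConfigError, match="at most 2 feasible"):
            ms_ssim_loss(np.zeros((32, 32)), np.zeros((32, 32)),
                         MsSsimConfig(num_scales=4))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ms_ssim_loss(np.zeros((16, 16)), np.zeros((16, 17)),
                         MsSsimConfig(num_scales=1, window_size=5))


class TestFocal:
    def test_zero_focusing_parameter_reduces_to_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(4), size=(2, 8, 8)).transpose(0, 3, 1, 2)
        labels = rng.integers(0, 4, (2, 8, 8))
        target = one_hot(labels, 4)
        focal = float(focal_loss(probs, target, FocalConfig(gamma=0.0)).data)
        ce = -np.log(np.take_along_axis(
            probs, labels[:, None], axis=1)).mean(axis=(1, 2, 3)).mean()
        assert focal == pytest.approx(float(ce), rel=1e-6)

    def test_perfect_prediction_has_zero_loss(self):
        labels = np.zeros((1, 4, 4), dtype=int)
        target = one_hot(labels, 2)
        assert float(focal_loss(target, target).data) == pytest.approx(0.0, abs=1e-6)

    def test_single_pixel_hand_value(self):
        # Yt = 1, Yp = 0.5, gamma = 2  ->  (1 - 0.5)^2 * (-log 0.5)
        probs = np.array([[[[0.5]], [[0.5]]]])
        target = np.array([[[[1.0]], [[0.0]]]])
        val = float(focal_loss(probs, target, FocalConfig(gamma=2.0)).data)
        assert val == pytest.approx(0.25 * -np.log(0.5), rel=1e-6)


class TestTversky:
    def test_perfect_binary_prediction_has_zero_loss(self):
        t = np.zeros((8, 8))
        t[2:5, 2:5] = 1
        assert float(tversky_loss(t, t).data) == pytest.approx(0.0)

    def test_balanced_weights_reduce_to_soft_dice_with_unit_smoothing(self, rng):
        p = rng.random((10, 10))
        t = (rng.random((10, 10)) > 0.6).astype(float)
        ours = float(tversky_loss(p, t, TverskyConfig(alpha=0.5)).data)
        inter = (p * t).sum()
        dice = 1.0 - (2 * inter + 2.0) / (p.sum() + t.sum() + 2.0)
        assert ours == pytest.approx(float(dice), rel=1e-6)

    def test_hand_value_with_two_errors_each_way(self):
        # TP=2, FN=2, FP=2, alpha=beta=0.5 -> 1 - 3/5 = 0.4
        t = np.zeros(10)
        t[:4] = 1
        p = np.zeros(10)
        p[:2] = 1    # two true positives
        p[4:6] = 1   # two false positives
        val = float(tversky_loss(p, t, TverskyConfig(alpha=0.5)).data)
        assert val == pytest.approx(0.4, abs=1e-9)

    def test_monotone_in_number_of_flipped_pixels(self):
        t = np.zeros((16, 16))
        t[4:10, 4:10] = 1
        losses = []
        for k in range(11):
            p = t.copy().ravel()
            p[:k] = 1 - p[:k]
            losses.append(float(tversky_loss(p.reshape(16, 16), t).data))
        assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))


class TestMixed:
    def test_default_weights_match_stated_ratios(self):
        w = LossWeights()
        assert w.w_msssim == 5.0
        assert w.w_focal == 3.0 * w.w_tversky

    def test_total_is_weighted_sum_of_components(self, rng):
        probs = rng.dirichlet(np.ones(6), size=(1, 48, 48)).transpose(0, 3, 1, 2)
        labels = rng.integers(0, 6, (1, 48, 48))
        target = one_hot(labels, 6)
        cfg = MixedLossConfig(msssim=MsSsimConfig(num_scales=2))
        total, parts = mixed_loss(probs, target, cfg)
        expected = 5.0 * parts["msssim"] + 3.0 * parts["focal"] + 1.0 * parts["tversky"]
        assert float(total.data) == pytest.approx(expected, rel=1e-6)

    def test_components_match_independent_calls(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(1, 32, 32)).transpose(0, 3, 1, 2)
        labels = rng.integers(0, 3, (1, 32, 32))
        target = one_hot(labels, 3)
        cfg = MixedLossConfig(msssim=MsSsimConfig(num_scales=1))
        _, parts = mixed_loss(probs, target, cfg)
        ms = np.mean([float(ms_ssim_loss(probs[:, k], target[:, k], cfg.msssim).data)
                      for k in (1, 2)])
        tv = np.mean([float(tversky_loss(probs[:, k], target[:, k], cfg.tversky).data)
                      for k in (1, 2)])
        fo = float(focal_loss(probs, target, cfg.focal).data)
        assert parts["msssim"] == pytest.approx(ms, rel=1e-6)
        assert parts["tversky"] == pytest.approx(tv, rel=1e-6)
        assert parts["focal"] == pytest.approx(fo, rel=1e-6)

    def test_perfect_one_hot_prediction_has_zero_total(self):
        labels = np.zeros((1, 48, 48), dtype=int)
        labels[0, 8:24, 8:24] = 1
        target = one_hot(labels, 3)
        cfg = MixedLossConfig(msssim=MsSsimConfig(num_scales=2))
        total, _ = mixed_loss(target, target, cfg)
        assert float(total.data) == pytest.approx(0.0, abs=1e-5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(InvalidConfigError):
            LossWeights(0.0, 0.0, 0.0)


class TestGradients:
    @pytest.mark.parametrize("component", ["msssim", "focal", "tversky"])
    def test_analytic_gradient_matches_finite_differences(self, component, rng):
        p0 = rng.uniform(0.05, 0.95, size=(8, 8))
        t = (rng.random((8, 8)) > 0.5).astype(float)

        def value(p):
            if component == "msssim":
                return float(ms_ssim_loss(
                    Tensor(p), t, MsSsimConfig(num_scales=1, window_size=5)).data)
            if component == "tversky":
                return float(tversky_loss(Tensor(p), t).data)
            probs = Tensor(np.stack([p, 1 - p])[None])
            target = np.stack([t, 1 - t])[None]
            return float(focal_loss(probs, target).data)

        num = numerical_grad(value, p0)
        tp = Tensor(p0, requires_grad=True)
        if component == "msssim":
            out = ms_ssim_loss(tp, t, MsSsimConfig(num_scales=1, window_size=5))
        elif component == "tversky":
            out = tversky_loss(tp, t)
        else:
            out = focal_loss(_two_class(tp), np.stack([t, 1 - t])[None])
        out.backward()
        assert np.allclose(tp.grad, num, rtol=1e-3, atol=1e-6)


def _two_class(tp):
    from natseg.autodiff import concat
    p = tp.reshape(1, 1, *tp.shape)
    return concat([p, 1.0 - p], axis=1)
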