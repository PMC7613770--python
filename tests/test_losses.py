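"""Loss terms: closed-form values, coefficient identities, gradient flow."""

import numpy as np
import pytest

from stereomt.nn import Tensor
from stereomt.losses import (
    LossWeights, disparity_supervised_loss, multitask_loss, photometric_loss,
    segmentation_loss, self_supervised_disparity_loss, smooth_l1,
    smoothness_loss, soft_dice_loss, ssim_loss, wbce,
)
from stereomt.synthetic import generate_fronto_scene

from conftest import analytic_grad, finite_difference_grad


class TestSmoothL1:
    @pytest.mark.parametrize("x,expected", [
        (0.5, 0.125), (2.0, 1.5), (1.0, 0.5), (-0.5, 0.125), (-2.0, 1.5),
    ])
    def test_closed_form(self, x, expected):
        assert smooth_l1(np.float32(x)).item() == pytest.approx(expected, abs=1e-6)

    def test_continuous_at_one(self):
        lo = smooth_l1(np.float32(1 - 1e-4)).item()
        hi = smooth_l1(np.float32(1 + 1e-4)).item()
        assert abs(lo - hi) < 1e-3


class TestSupervisedDisparityLoss:
    def test_perfect_prediction_is_zero(self, rng):
        gt = rng.uniform(0, 30, size=(16, 16)).astype(np.float32)
        pred = {1: Tensor(gt[None, None])}
        assert disparity_supervised_loss(pred, gt).item() == pytest.approx(0.0)

    def test_constant_offset_half(self, rng):
        gt = rng.uniform(0, 30, size=(16, 16)).astype(np.float32)
        pred = {1: Tensor(gt[None, None] + 0.5)}
        assert disparity_supervised_loss(pred, gt).item() == pytest.approx(0.125, abs=1e-6)

    def test_out_of_range_ground_truth_ignored(self, rng):
        gt = rng.uniform(0, 30, size=(8, 8)).astype(np.float32)
        gt[0, :4] = 321.0
        pred_map = gt * 0 + 3.0
        loss_all = disparity_supervised_loss({1: Tensor(pred_map[None, None])}, gt)
        keep = gt <= 320
        loss_masked = disparity_supervised_loss(
            {1: Tensor(pred_map[None, None])}, gt, valid=keep)
        assert loss_all.item() == pytest.approx(loss_masked.item(), rel=1e-6)

    def test_no_valid_pixels_returns_zero(self):
        gt = np.full((4, 4), 400.0, dtype=np.float32)
        loss = disparity_supervised_loss({1: Tensor(np.zeros((1, 1, 4, 4)))}, gt)
        assert loss.item() == 0.0

    def test_coarse_scale_upscaled_before_comparison(self):
        # constant gt 8 at full res; S2 prediction of 4 is correct after x2
        gt = np.full((16, 16), 8.0, dtype=np.float32)
        pred = {2: Tensor(np.full((1, 1, 8, 8), 4.0, dtype=np.float32))}
        assert disparity_supervised_loss(pred, gt).item() == pytest.approx(0.0, abs=1e-6)


class TestSegmentationLosses:
    def test_wbce_single_pixel_closed_form(self):
        val = wbce(np.ones((1, 1)), np.full((1, 1), 0.5), beta=2.0).item()
        assert val == pytest.approx(2 * np.log(2), abs=1e-5)

    def test_wbce_perfect_prediction_near_zero(self, rng):
        s = (rng.uniform(size=(8, 8)) > 0.5).astype(np.float32)
        assert wbce(s, s, beta=2.0).item() <= 1e-5

    def test_wbce_beta_scales_foreground_only(self, rng):
        s = (rng.uniform(size=(8, 8)) > 0.5).astype(np.float32)
        p = rng.uniform(0.2, 0.8, size=(8, 8)).astype(np.float32)
        n = s.size
        fg = -np.mean(s * np.log(p))
        bg = -np.mean((1 - s) * np.log(1 - p))
        for beta in (1.0, 2.0, 4.0):
            assert wbce(s, p, beta).item() == pytest.approx(beta * fg + bg, rel=1e-4)

    def test_wbce_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            wbce(np.ones((2, 2)), np.full((2, 2), 0.5), beta=0.0)

    def test_dice_identical_masks(self):
        s = np.ones((4, 4), dtype=np.float32)
        assert soft_dice_loss(s, s).item() == pytest.approx(0.0, abs=1e-6)

    def test_dice_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=np.float32)
        b = np.zeros((4, 4), dtype=np.float32)
        a[:2], b[2:] = 1.0, 1.0
        expected = 1.0 - 1e-5 / (16 + 1e-5)
        assert soft_dice_loss(a, b).item() == pytest.approx(expected, rel=1e-6)

    def test_dice_both_empty_is_zero(self):
        z = np.zeros((4, 4), dtype=np.float32)
        assert soft_dice_loss(z, z).item() == pytest.approx(0.0, abs=1e-7)

    def test_segmentation_loss_is_equal_weight_sum(self, rng):
        s = (rng.uniform(size=(8, 8)) > 0.5).astype(np.float32)
        p = rng.uniform(0.1, 0.9, size=(8, 8)).astype(np.float32)
        w = LossWeights()
        expected = 0.5 * wbce(s, p, w.beta_wbce).item() \
            + 0.5 * soft_dice_loss(s, p, w.dice_eps).item()
        assert segmentation_loss(s, p, w).item() == pytest.approx(expected, rel=1e-6)

    def test_segmentation_loss_decreases_toward_target(self, rng):
        s = (rng.uniform(size=(8, 8)) > 0.5).astype(np.float32)
        p0 = rng.uniform(0.3, 0.7, size=(8, 8)).astype(np.float32)
        values = []
        for t in (0.0, 0.5, 1.0):
            p = np.clip((1 - t) * p0 + t * s, 1e-6, 1 - 1e-6)
            values.append(segmentation_loss(s, p).item())
        assert values[0] > values[1] > values[2]


class TestSelfSupervisedTerms:
    def test_ssim_identical_images_zero(self, rng):
        img = rng.uniform(size=(16, 16, 3)).astype(np.float32)
        assert ssim_loss(img, img).item() == pytest.approx(0.0, abs=1e-6)

    def test_ssim_constant_images_closed_form(self):
        # means 0.2 / 0.8, zero variances: luminance term only
        a = np.full((16, 16, 3), 0.2, dtype=np.float32)
        b = np.full((16, 16, 3), 0.8, dtype=np.float32)
        ssim = (2 * 0.2 * 0.8 + 1e-4) / (0.2 ** 2 + 0.8 ** 2 + 1e-4)
        expected = (1 - ssim) / 2  # = 0.2646668...
        assert ssim_loss(a, b).item() == pytest.approx(expected, abs=1e-4)

    def test_ssim_loss_in_unit_interval(self, rng):
        for _ in range(5):
            a = rng.uniform(size=(16, 16, 3)).astype(np.float32)
            b = rng.uniform(size=(16, 16, 3)).astype(np.float32)
            assert 0.0 <= ssim_loss(a, b).item() <= 1.0

    def test_ssim_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim_loss(np.zeros((8, 8, 3)), np.zeros((8, 8, 3)), window=11)

    def test_photometric_matches_smooth_l1_composition(self, rng):
        a = rng.uniform(size=(8, 8, 3)).astype(np.float32)
        b = rng.uniform(size=(8, 8, 3)).astype(np.float32)
        assert photometric_loss(a, b).item() == pytest.approx(
            smooth_l1(Tensor(a - b)).mean().item(), rel=1e-6)
        assert photometric_loss(a, a).item() == 0.0
        assert photometric_loss(a, a + 0.5).item() == pytest.approx(0.125, abs=1e-6)

    def test_smoothness_zero_for_constant_disparity(self, rng):
        img = rng.uniform(size=(8, 8, 3)).astype(np.float32)
        assert smoothness_loss(img, np.full((8, 8), 7.0)).item() == pytest.approx(0.0)

    def test_smoothness_ramp_closed_form(self):
        # constant image -> exp(0) = 1; x-ramp of slope s gives s / 320
        img = np.full((8, 8, 3), 0.4, dtype=np.float32)
        slope = 2.0
        d = np.tile(np.arange(8, dtype=np.float32) * slope, (8, 1))
        assert smoothness_loss(img, d).item() == pytest.approx(slope / 320, rel=1e-5)

    def test_smoothness_edge_damping_monotone(self):
        slope = 2.0
        d = np.tile(np.arange(8, dtype=np.float32) * slope, (8, 1))
        flat = np.full((8, 8, 3), 0.5, dtype=np.float32)
        ramp = np.tile(np.linspace(0, 1, 8, dtype=np.float32)[None, :, None], (8, 1, 3))
        assert smoothness_loss(ramp, d).item() <= smoothness_loss(flat, d).item()

    def test_coefficient_collapse_to_photometric(self, rng):
        s = generate_fronto_scene(64, 64, 6.0, 2)
        w = LossWeights(alpha_ss=1.0, beta_ss=1.0)
        total = self_supervised_disparity_loss(s.left, s.right, s.disparity, w)
        from stereomt.disparity import warp_right_to_left
        recon = warp_right_to_left(s.right, s.disparity)
        assert total.item() == pytest.approx(
            photometric_loss(s.left, recon).item(), rel=1e-5)

    def test_default_weights_definition(self, rng):
        s = generate_fronto_scene(64, 64, 5.0, 3)
        d = s.disparity + rng.uniform(-1, 1, size=s.disparity.shape).astype(np.float32)
        d = np.clip(d, 0, None)
        from stereomt.disparity import warp_right_to_left
        recon = warp_right_to_left(s.right, d)
        w = LossWeights()
        expected = 0.7 * (0.9 * photometric_loss(s.left, recon).item()
                          + 0.1 * ssim_loss(s.left, recon).item()) \
            + 0.3 * smoothness_loss(s.left, d).item()
        got = self_supervised_disparity_loss(s.left, s.right, d, w).item()
        assert got == pytest.approx(expected, rel=1e-5)

    def test_ground_truth_disparity_gives_tiny_photometric_term(self):
        s = generate_fronto_scene(64, 64, 8.0, 11)
        from stereomt.disparity import warp_right_to_left
        recon = warp_right_to_left(s.right, s.disparity)
        # integer shift: reconstruction is exact away from the border
        assert photometric_loss(s.left[:, 8:], recon[:, 8:]).item() < 1e-3
        assert smoothness_loss(s.left, s.disparity).item() == pytest.approx(0.0)

    def test_gradient_flows_to_disparity(self, rng):
        s = generate_fronto_scene(64, 64, 3.0, 5)
        left = s.left[:6, :6]
        right = s.right[:6, :6]
        d = Tensor(rng.uniform(1.2, 2.8, size=(1, 1, 6, 6)).astype(np.float32),
                   requires_grad=True)
        w = LossWeights(ssim_window=5)
        f = lambda: self_supervised_disparity_loss(left, right, d, w)
        ag = analytic_grad(f, d)
        assert np.abs(ag).max() > 0
        ng = finite_difference_grad(f, d, eps=3e-3)
        assert np.linalg.norm(ag - ng) / np.linalg.norm(ng) < 5e-2


class TestMultitaskCombination:
    @pytest.mark.parametrize("d,s,alpha,expected", [
        (1.0, 0.0, 0.2, 0.2),
        (0.0, 1.0, 0.2, 0.8),
        (0.5, 0.5, 0.35, 0.5),
    ])
    def test_convex_combination(self, d, s, alpha, expected):
        assert multitask_loss(d, s, alpha).item() == pytest.approx(expected, abs=1e-7)


def test_loss_weight_validation():
    with pytest.raises(ValueError):
        LossWeights(alpha_mt=1.5)
    with pytest.raises(ValueError):
        LossWeights(dice_eps=0.0)
    defaults = LossWeights()
    assert defaults.beta_wbce == pytest.approx((1 - 0.15) / 0.15)
    assert defaults.ssim_c1 == pytest.approx(1e-4)
    assert defaults.ssim_c2 == pytest.approx(9e-4)
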