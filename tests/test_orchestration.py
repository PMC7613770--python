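"""Training orchestration: augmentation, phases, modularity, checkpoints."""

import numpy as np
import pytest

from stereomt import nn
from stereomt.nn import Tensor
from stereomt.losses import LossWeights
from stereomt.model import load_checkpoint, model_factory, save_checkpoint
from stereomt.synthetic import generate_fronto_scene, warp_right_to_left_numpy
from stereomt.train import (
    TrainConfig, augment, make_fronto_dataset, make_segmentation_dataset,
    multitask_phase_loss, run_phase,
)

IDENTITY = dict(normalization_mean=(0.0, 0.0, 0.0),
                normalization_std=(1.0, 1.0, 1.0))


class TestAugment:
    def test_vertical_flip_preserves_rectification(self):
        sample = generate_fronto_scene(64, 64, 6.0, 3)
        cfg = TrainConfig(vflip_prob=1.0, **IDENTITY)
        out = augment(sample, cfg, np.random.default_rng(0))
        rec = warp_right_to_left_numpy(out.right, out.disparity)
        assert np.abs(rec - out.left)[out.valid].mean() < 0.02

    def test_crop_keeps_disparity_values(self):
        sample = generate_fronto_scene(64, 96, 9.0, 3)
        cfg = TrainConfig(crop=(64, 32), vflip_prob=0.0, **IDENTITY)
        out = augment(sample, cfg, np.random.default_rng(5))
        assert out.shape == (32, 64)
        np.testing.assert_array_equal(out.disparity, 9.0)

    def test_same_rng_state_reproduces(self):
        sample = generate_fronto_scene(64, 96, 9.0, 3)
        cfg = TrainConfig(crop=(32, 32), vflip_prob=0.5, **IDENTITY)
        a = augment(sample, cfg, np.random.default_rng(11))
        b = augment(sample, cfg, np.random.default_rng(11))
        np.testing.assert_array_equal(a.left, b.left)
        np.testing.assert_array_equal(a.disparity, b.disparity)

    def test_oversized_crop_rejected(self):
        sample = generate_fronto_scene(64, 64, 4.0, 1)
        cfg = TrainConfig(crop=(96, 64), **IDENTITY)
        with pytest.raises(ValueError):
            augment(sample, cfg, np.random.default_rng(0))

    def test_normalization_applied(self):
        sample = generate_fronto_scene(64, 64, 4.0, 1)
        cfg = TrainConfig(vflip_prob=0.0,
                          normalization_mean=(0.5, 0.5, 0.5),
                          normalization_std=(0.25, 0.25, 0.25))
        out = augment(sample, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out.left, (sample.left - 0.5) / 0.25,
                                   atol=1e-6)


class TestConfig:
    def test_bad_phase_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(phase="warmup")

    def test_crop_must_be_divisible_by_32(self):
        with pytest.raises(ValueError):
            TrainConfig(crop=(100, 64))

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "phase: finetune_seg\nvariant: tiny\nepochs: 3\n"
            "crop: [64, 32]\nloss_weights:\n  alpha_mt: 0.3\n")
        cfg = TrainConfig.from_yaml(p)
        assert cfg.phase == "finetune_seg" and cfg.crop == (64, 32)
        assert cfg.loss_weights.alpha_mt == 0.3


class TestModelFactory:
    def test_empty_heads_rejected(self):
        with pytest.raises(ValueError):
            model_factory("tiny", set())

    def test_segmentation_only_consumes_single_view(self):
        model = model_factory("tiny", {"segmentation"}, seed=0).eval()
        img = np.random.default_rng(0).uniform(size=(64, 64, 3)).astype(np.float32)
        model.encoder_calls = 0
        with nn.no_grad():
            out = model(img)
        assert "segmentation" in out and "disparity" not in out
        assert model.encoder_calls == 1

    def test_multitask_encoder_runs_once_per_view(self):
        model = model_factory("tiny", {"disparity", "segmentation"}, seed=0).eval()
        rng = np.random.default_rng(0)
        left = rng.uniform(size=(64, 64, 3)).astype(np.float32)
        right = rng.uniform(size=(64, 64, 3)).astype(np.float32)
        model.encoder_calls = 0
        with nn.no_grad():
            out = model(left, right)
        assert model.encoder_calls == 2  # once per view, shared across heads
        assert set(out) == {"disparity", "segmentation"}

    def test_removing_one_head_leaves_other_output_unchanged(self):
        rng = np.random.default_rng(0)
        left = rng.uniform(size=(64, 64, 3)).astype(np.float32)
        right = rng.uniform(size=(64, 64, 3)).astype(np.float32)
        multi = model_factory("tiny", {"disparity", "segmentation"}, seed=7).eval()
        solo = model_factory("tiny", {"disparity"}, seed=99).eval()
        solo.encoder.load_state_dict(multi.encoder.state_dict())
        solo.disparity_head.load_state_dict(multi.disparity_head.state_dict())
        with nn.no_grad():
            a = multi(left, right)["disparity"]
            b = solo(left, right)["disparity"]
        for scale in a.scales():
            np.testing.assert_array_equal(a[scale].data, b[scale].data)

    def test_checkpoint_interchange_single_to_multitask(self, tmp_path):
        disp_only = model_factory("tiny", {"disparity"}, seed=1)
        path = tmp_path / "disp.npz"
        save_checkpoint(disp_only, path)
        multi = model_factory("tiny", {"disparity", "segmentation"}, seed=2)
        seg_before = multi.segmentation_head.state_dict()
        load_checkpoint(path, multi)
        np.testing.assert_array_equal(
            multi.encoder.state_dict()["block2._0.weight"],
            disp_only.encoder.state_dict()["block2._0.weight"])
        seg_after = multi.segmentation_head.state_dict()
        for key in seg_before:
            np.testing.assert_array_equal(seg_before[key], seg_after[key])

    def test_checkpoint_variant_mismatch_rejected(self, tmp_path):
        model = model_factory("tiny", {"disparity"}, seed=1)
        path = tmp_path / "m.npz"
        save_checkpoint(model, path)
        other = model_factory("lightweight", {"disparity"}, seed=1)
        with pytest.raises(ValueError, match="variant"):
            load_checkpoint(path, other)


class TestRunPhase:
    def test_phase_dataset_mismatch_detected_before_training(self):
        model = model_factory("tiny", {"disparity"}, seed=0)
        dataset = make_segmentation_dataset(2, seed=0)
        ds = [type(s)(left=s.left, right=s.right, mask=s.mask) for s in dataset]
        cfg = TrainConfig(phase="pretrain", variant="tiny", **IDENTITY)
        with pytest.raises(ValueError, match="disparity"):
            run_phase(model, ds, cfg)

    def test_zero_learning_rate_is_null_update(self):
        model = model_factory("tiny", {"disparity"}, seed=3)
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if "running" not in k}
        dataset = make_fronto_dataset(4, seed=1)
        cfg = TrainConfig(phase="pretrain", variant="tiny", epochs=1,
                          batch_size=4, lr_schedule="constant", constant_lr=0.0,
                          weight_decay=0.0, vflip_prob=0.0, **IDENTITY)
        model, _ = run_phase(model, dataset, cfg, steps=2)
        after = model.state_dict()
        for key, val in before.items():
            np.testing.assert_array_equal(val, after[key], err_msg=key)

    def test_finetune_seg_leaves_disparity_head_untouched(self):
        model = model_factory("tiny", {"disparity", "segmentation"}, seed=4)
        before = {k: v.copy() for k, v in model.disparity_head.state_dict().items()}
        dataset = make_segmentation_dataset(4, seed=2)
        cfg = TrainConfig(phase="finetune_seg", variant="tiny", epochs=3,
                          batch_size=4, lr_schedule="constant",
                          constant_lr=1e-3, vflip_prob=0.0, **IDENTITY)
        model, log = run_phase(model, dataset, cfg, steps=3)
        after = model.disparity_head.state_dict()
        for key, val in before.items():
            np.testing.assert_array_equal(val, after[key], err_msg=key)
        assert len(log["step_losses"]) == 3

    def test_multitask_loss_touches_only_full_resolution_scale(self):
        """Coarse pyramid scales get no direct term in the joint objective."""
        rng = np.random.default_rng(0)
        sample = generate_fronto_scene(64, 64, 6.0, 9)
        pyramid = {}
        for scale in (1, 2, 3, 4, 5, 6):
            hw = 64 // 2 ** (scale - 1)
            pyramid[scale] = Tensor(
                rng.uniform(0, 4, size=(1, 1, hw, hw)).astype(np.float32),
                requires_grad=True)
        logits = Tensor(rng.normal(size=(1, 1, 64, 64)).astype(np.float32),
                        requires_grad=True)
        mask = Tensor(rng.uniform(size=(1, 1, 64, 64)).astype(np.float32) > 0.8)
        left = Tensor(sample.left.transpose(2, 0, 1)[None])
        right = Tensor(sample.right.transpose(2, 0, 1)[None])
        loss = multitask_phase_loss(pyramid, logits, left, right,
                                    Tensor(mask.data.astype(np.float32)),
                                    LossWeights())
        loss.backward()
        assert pyramid[1].grad is not None and np.abs(pyramid[1].grad).max() > 0
        for scale in (2, 3, 4, 5, 6):
            assert pyramid[scale].grad is None
        assert logits.grad is not None

    def test_training_loss_decreases_on_small_overfit(self):
        model = model_factory("tiny", {"disparity", "segmentation"}, seed=5)
        dataset = make_segmentation_dataset(4, seed=3)
        cfg = TrainConfig(phase="finetune_seg", variant="tiny", epochs=15,
                          batch_size=4, lr_schedule="constant",
                          constant_lr=2e-3, vflip_prob=0.0, **IDENTITY)
        model, log = run_phase(model, dataset, cfg)
        losses = log["step_losses"]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])
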