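"""Phased training: disparity pre-training, multi-task learning, fine-tuning.

Training proceeds in phases over the same shared-encoder model:

* ``pretrain`` — full supervision of the disparity pyramid at every scale;
  the segmentation head is absent.
* ``multitask`` — the disparity output is self-supervised at S1 only while
  the segmentation head is fully supervised; the two objectives mix with
  weight alpha_mt on the disparity side.
* ``finetune_disp`` / ``finetune_seg`` — single-task objectives; the other
  head's weights (including batch-norm state) are left untouched.

One master seed drives weight initialization, data order and augmentation.
Per-epoch losses and metrics are appended to a JSON-lines log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import Tensor
from .losses import (
    LossWeights, disparity_supervised_loss, segmentation_loss,
    self_supervised_disparity_loss, multitask_loss,
)
from .metrics import epe, iou
from .model import MultiTaskModel, model_factory, save_checkpoint
from .synthetic import StereoSample, generate_fronto_scene, generate_smooth_scene, \
    generate_instrument_mask

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "augment", "run_phase", "multitask_phase_loss",
    "run_self_supervised_adaptation",
    "make_fronto_dataset", "make_segmentation_dataset", "evaluate_disparity",
]

PHASES = ("pretrain", "multitask", "finetune_disp", "finetune_seg")

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)
IDENTITY_STATS = ((0.0, 0.0, 0.0), (1.0, 1.0, 1.0))


@dataclass
class TrainConfig:
    phase: str = "pretrain"
    variant: str = "lightweight"
    epochs: int = 1
    batch_size: int = 8
    lr_schedule: str = "one_cycle"  # or "constant"
    max_lr: float = 1e-3
    constant_lr: float = 1e-4
    weight_decay: float = 1e-4
    optimizer_betas: tuple[float, float] = (0.9, 0.999)
    crop: tuple[int, int] | None = None  # (width, height)
    vflip_prob: float = 0.5
    normalization_mean: tuple[float, float, float] = IMAGENET_MEAN
    normalization_std: tuple[float, float, float] = IMAGENET_STD
    seed: int = 42
    max_disparity: float = 320.0
    cascade_noise_px: float = 0.0  # train-time prealignment perturbation
    loss_weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase '{self.phase}' (choose from {PHASES})")
        if self.crop is not None:
            cw, ch = self.crop
            if cw % 32 or ch % 32:
                raise ValueError(f"crop dims {self.crop} must be divisible by 32")
        if not 0.0 <= self.vflip_prob <= 1.0:
            raise ValueError("vflip_prob must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        lw = raw.pop("loss_weights", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if lw:
            cfg.loss_weights = LossWeights(**lw)
        return cfg


def _normalize(image: np.ndarray, mean, std) -> np.ndarray:
    return ((image - np.asarray(mean, dtype=np.float32))
            / np.asarray(std, dtype=np.float32)).astype(np.float32)


def augment(sample: StereoSample, config: TrainConfig,
            rng: np.random.Generator, normalize: bool = True) -> StereoSample:
    """Random crop + vertical flip + color normalization.

    The same crop window and flip decision are applied to every field, so
    the rectification contract (rows aligned, disparity values unchanged)
    is preserved.
    """
    h, w = sample.shape
    left, right = sample.left, sample.right
    disp, valid, mask = sample.disparity, sample.valid, sample.mask
    if config.crop is not None:
        cw, ch = config.crop
        if cw > w or ch > h:
            raise ValueError(f"crop {config.crop} larger than sample {(w, h)}")
        x0 = int(rng.integers(0, w - cw + 1))
        y0 = int(rng.integers(0, h - ch + 1))
        sl = np.s_[y0:y0 + ch, x0:x0 + cw]
        left, right = left[sl], right[sl]
        disp = None if disp is None else disp[sl]
        valid = None if valid is None else valid[sl]
        mask = None if mask is None else mask[sl]
    if rng.uniform() < config.vflip_prob:
        left, right = left[::-1].copy(), right[::-1].copy()
        disp = None if disp is None else disp[::-1].copy()
        valid = None if valid is None else valid[::-1].copy()
        mask = None if mask is None else mask[::-1].copy()
    if normalize:
        mean, std = config.normalization_mean, config.normalization_std
        left = _normalize(left, mean, std)
        right = _normalize(right, mean, std)
    return StereoSample(left=np.ascontiguousarray(left),
                        right=np.ascontiguousarray(right),
                        disparity=disp, valid=valid, mask=mask)


def _batch_tensors(samples: list[StereoSample], config: TrainConfig):
    """Stack augmented samples into network inputs and raw-loss targets."""
    left_net = np.stack([_normalize(s.left, config.normalization_mean,
                                    config.normalization_std) for s in samples])
    right_net = np.stack([_normalize(s.right, config.normalization_mean,
                                     config.normalization_std) for s in samples])
    out = {
        "left_net": Tensor(left_net.transpose(0, 3, 1, 2)),
        "right_net": Tensor(right_net.transpose(0, 3, 1, 2)),
        "left_raw": Tensor(np.stack([s.left for s in samples]).transpose(0, 3, 1, 2)),
        "right_raw": Tensor(np.stack([s.right for s in samples]).transpose(0, 3, 1, 2)),
    }
    if all(s.disparity is not None for s in samples):
        out["disparity"] = np.stack([s.disparity for s in samples])
        out["valid"] = np.stack([
            s.valid if s.valid is not None else np.ones(s.shape, bool) for s in samples
        ])
    if all(s.mask is not None for s in samples):
        out["mask"] = Tensor(np.stack([s.mask for s in samples])
                             .astype(np.float32)[:, None])
    return out


def multitask_phase_loss(disparity_pyramid, seg_logits, left_raw, right_raw,
                         mask, weights: LossWeights) -> Tensor:
    """Joint objective: S1-only disparity self-supervision + supervised
    segmentation.

    Only the full-resolution entry of the pyramid enters the loss; coarser
    scales receive no direct supervision in this phase.
    """
    disparity = getattr(disparity_pyramid, "disparity", disparity_pyramid)
    ss = self_supervised_disparity_loss(left_raw, right_raw, disparity[1], weights)
    seg = segmentation_loss(mask, seg_logits.sigmoid(), weights)
    return multitask_loss(ss, seg, weights.alpha_mt)


def _phase_requirements(phase: str, dataset: list[StereoSample], model: MultiTaskModel):
    need_disp = phase in ("pretrain", "finetune_disp")
    need_mask = phase in ("multitask", "finetune_seg")
    if need_disp and not all(s.disparity is not None for s in dataset):
        raise ValueError(f"phase '{phase}' requires disparity ground truth")
    if need_mask and not all(s.mask is not None for s in dataset):
        raise ValueError(f"phase '{phase}' requires instrument masks")
    if phase != "finetune_seg" and "disparity" not in model.heads:
        raise ValueError(f"phase '{phase}' requires a disparity head")
    if need_mask and "segmentation" not in model.heads:
        raise ValueError(f"phase '{phase}' requires a segmentation head")


def _trainable_params(model: MultiTaskModel, phase: str):
    scopes = [("encoder.", model.encoder)]
    if phase in ("pretrain", "finetune_disp", "multitask") and "disparity" in model.heads:
        scopes.append(("disparity_head.", model.disparity_head))
    if phase in ("multitask", "finetune_seg") and "segmentation" in model.heads:
        scopes.append(("segmentation_head.", model.segmentation_head))
    params = []
    for _, scope in scopes:
        params.extend(scope.parameters())
    return params, [name for name, _ in scopes]


def run_phase(model: MultiTaskModel, dataset: list[StereoSample],
              config: TrainConfig, steps: int | None = None):
    """Train ``model`` for one phase; returns (model, per-epoch metric log).

    ``steps`` optionally caps the total number of optimizer steps (for
    small-scale experiments); otherwise epochs * ceil(n / batch) steps run.
    """
    _phase_requirements(config.phase, dataset, model)
    rng = np.random.default_rng(config.seed)
    params, scope_names = _trainable_params(model, config.phase)
    steps_per_epoch = max(1, int(np.ceil(len(dataset) / config.batch_size)))
    total_steps = config.epochs * steps_per_epoch
    if steps is not None:
        total_steps = min(total_steps, steps)
    opt = nn.AdamW(params, lr=config.max_lr, betas=config.optimizer_betas,
                   weight_decay=config.weight_decay)
    log: list[dict] = []
    weights = config.loss_weights
    model.train()
    step = 0
    epoch = 0
    losses_epoch: list[float] = []
    step_losses: list[float] = []
    while step < total_steps:
        order = rng.permutation(len(dataset))
        for b0 in range(0, len(dataset), config.batch_size):
            if step >= total_steps:
                break
            idx = order[b0:b0 + config.batch_size]
            samples = [augment(dataset[i], config, rng, normalize=False)
                       for i in idx]
            batch = _batch_tensors(samples, config)
            if config.lr_schedule == "one_cycle":
                opt.lr = nn.one_cycle_lr(step, total_steps, config.max_lr)
            else:
                opt.lr = config.constant_lr
            loss = _phase_step_loss(model, batch, config.phase, weights,
                                    config.max_disparity,
                                    config.cascade_noise_px, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses_epoch.append(loss.item())
            step_losses.append(loss.item())
            step += 1
        entry = {"epoch": epoch, "step": step, "lr": opt.lr,
                 "phase": config.phase, "scopes": scope_names,
                 "loss": float(np.mean(losses_epoch))}
        log.append(entry)
        if config.log_path:
            with open(config.log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        if config.checkpoint_dir:
            out = Path(config.checkpoint_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, out / f"{config.phase}-epoch{epoch:04d}.npz")
        losses_epoch = []
        epoch += 1
    model.eval()
    return model, {"epochs": log, "step_losses": step_losses}


def _phase_step_loss(model, batch, phase, weights, max_disparity,
                     cascade_noise_px=0.0, rng=None):
    if phase in ("pretrain", "finetune_disp"):
        pyr = model.disparity_head(
            model.encode(batch["left_net"]), model.encode(batch["right_net"]),
            batch["left_net"], cascade_noise_px=cascade_noise_px,
            noise_rng=rng,
        )
        return disparity_supervised_loss(pyr, batch["disparity"], batch["valid"],
                                         max_disparity)
    if phase == "finetune_seg":
        logits = model.segmentation_head.decode_logits(model.encode(batch["left_net"]))
        return segmentation_loss(batch["mask"], logits.sigmoid(), weights)
    # multitask
    left_pyr = model.encode(batch["left_net"])
    right_pyr = model.encode(batch["right_net"])
    pyr = model.disparity_head(left_pyr, right_pyr, batch["left_net"])
    logits = model.segmentation_head.decode_logits(left_pyr)
    return multitask_phase_loss(pyr, logits, batch["left_raw"],
                                batch["right_raw"], batch["mask"], weights)


def run_self_supervised_adaptation(model: MultiTaskModel,
                                   dataset: list[StereoSample],
                                   config: TrainConfig,
                                   steps: int = 100,
                                   freeze_bn: bool = True) -> MultiTaskModel:
    """Adapt a trained disparity model with stereo self-supervision only.

    No ground truth enters: the photometric/SSIM/smoothness objective on the
    S1 output drives encoder and disparity head (the degenerate multi-task
    mode with the segmentation term switched off).  Used to adapt a
    pre-trained model to new scenes from rectified pairs alone.  By default
    batch-norm statistics stay frozen (evaluation mode), the usual practice
    when adapting a converged model on small batches.
    """
    rng = np.random.default_rng(config.seed)
    params = list(model.encoder.parameters()) + \
        list(model.disparity_head.parameters())
    opt = nn.AdamW(params, lr=config.constant_lr,
                   betas=config.optimizer_betas,
                   weight_decay=config.weight_decay)
    weights = config.loss_weights
    model.eval() if freeze_bn else model.train()
    for step in range(steps):
        idx = rng.choice(len(dataset), size=min(config.batch_size, len(dataset)),
                         replace=False)
        samples = [augment(dataset[i], config, rng, normalize=False) for i in idx]
        batch = _batch_tensors(samples, config)
        pyr = model.disparity_head(
            model.encode(batch["left_net"]), model.encode(batch["right_net"]),
            batch["left_net"])
        loss = self_supervised_disparity_loss(
            batch["left_raw"], batch["right_raw"], pyr[1], weights)
        opt.zero_grad()
        loss.backward()
        opt.step()
    model.eval()
    return model


# -- dataset builders --------------------------------------------------------

def make_fronto_dataset(n: int, height: int = 64, width: int = 64,
                        shift_range: tuple[float, float] = (4.0, 28.0),
                        seed: int = 0) -> list[StereoSample]:
    """Fronto-parallel scenes with shifts drawn uniformly from the range."""
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(*shift_range, size=n)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    return [generate_fronto_scene(height, width, float(s), int(sd))
            for s, sd in zip(shifts, seeds)]


def make_segmentation_dataset(n: int, height: int = 64, width: int = 64,
                              n_tools: int = 2, seed: int = 0) -> list[StereoSample]:
    """Textured frames paired with tool-like masks (monocular supervision)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        scene = generate_smooth_scene(height, width, 2, 10, int(rng.integers(2 ** 31)))
        mask = generate_instrument_mask(height, width, n_tools, int(rng.integers(2 ** 31)))
        # darken the tool region so the mask is visually grounded in the image
        left = scene.left.copy()
        left[mask] = 0.15 * left[mask] + 0.55
        right = scene.right
        out.append(StereoSample(left=left, right=right, disparity=scene.disparity,
                                valid=scene.valid, mask=mask))
    return out


def evaluate_disparity(model: MultiTaskModel, dataset: list[StereoSample],
                       config: TrainConfig) -> float:
    """Held-out mean EPE of the full-resolution output."""
    model.eval()
    errors = []
    with nn.no_grad():
        for s in dataset:
            left = _normalize(s.left, config.normalization_mean,
                              config.normalization_std)
            right = _normalize(s.right, config.normalization_mean,
                               config.normalization_std)
            pyr = model.predict_disparity(left, right)
            errors.append(epe(pyr.full_resolution(), s.disparity, s.valid))
    return float(np.mean(errors))
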