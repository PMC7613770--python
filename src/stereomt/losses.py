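"""Training objectives: supervised disparity, segmentation, self-supervision.

Four families of terms are provided, every one differentiable through the
autodiff engine so they can drive training directly:

* multi-scale supervised disparity loss — smooth-L1 between ground truth
  and each scale's prediction, after bilinearly up-sampling the prediction
  to full resolution and multiplying its values by the resolution ratio;
  pixels with ground truth above the 320 px search range are ignored, and
  the per-scale losses are averaged.
* segmentation loss — the equal-weight sum of a weighted binary
  cross-entropy (foreground weighted by beta, compensating the ~15 % tool
  coverage) and a soft dice loss with an epsilon of 1e-5.
* self-supervised stereo loss — the right image is warped to the left view
  by the predicted disparity; a smooth-L1 photometric term and an SSIM term
  (uniform 11x11 windows) compare the reconstruction to the left image, and
  an edge-aware smoothness term penalizes disparity gradients away from
  image edges after normalizing disparity by the 320 px search range.
  Occlusions are deliberately not masked.  Applied to the S1 output only.
* multi-task combination — alpha_mt * self-supervised disparity +
  (1 - alpha_mt) * segmentation.

The printed cross-entropy definition is an unnormalized sum; it is
normalized by pixel count here so that it stays on the same [0, 1]-ish
scale as the dice term and the stated mixing coefficients remain balanced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, as_tensor, ops

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights", "smooth_l1", "disparity_supervised_loss", "wbce",
    "soft_dice_loss", "segmentation_loss", "ssim_loss", "photometric_loss",
    "smoothness_loss", "self_supervised_disparity_loss", "multitask_loss",
]

_TOOL_COVERAGE = 0.15  # average fraction of tool pixels in training frames


@dataclass
class LossWeights:
    """Mixing coefficients and constants of all loss terms (defaults as used
    for multi-task training)."""

    alpha_mt: float = 0.2
    alpha_ss: float = 0.9
    beta_ss: float = 0.7
    beta_wbce: float = (1.0 - _TOOL_COVERAGE) / _TOOL_COVERAGE
    dice_eps: float = 1e-5
    max_disparity: float = 320.0
    ssim_c1: float = 0.01 ** 2
    ssim_c2: float = 0.03 ** 2
    ssim_window: int = 11

    def __post_init__(self):
        for name in ("alpha_mt", "alpha_ss", "beta_ss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dice_eps <= 0:
            raise ValueError("dice_eps must be positive")
        if self.beta_wbce <= 0:
            raise ValueError("beta_wbce must be positive")


def _img(x) -> Tensor:
    """Canonicalize an image to an NCHW tensor ((H,W,3)/(H,W) accepted)."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr.transpose(2, 0, 1)[None]
    return Tensor(arr)


def smooth_l1(w) -> Tensor:
    """Huber-style penalty: 0.5 w^2 for |w| < 1, |w| - 0.5 otherwise."""
    w = as_tensor(w)
    inner = Tensor((np.abs(w.data) < 1.0).astype(np.float32))
    return inner * (0.5 * w * w) + (1.0 - inner) * (w.abs() - 0.5)


def disparity_supervised_loss(pred, gt, valid=None,
                              max_disparity: float = 320.0) -> Tensor:
    """Mean over scales of masked smooth-L1 at full resolution.

    ``pred`` is a DisparityPyramid (or mapping scale -> NCHW tensor); each
    scale is bilinearly up-sampled to the ground-truth resolution and its
    values multiplied by the resolution ratio 2^(i-1) before comparison.
    Ground-truth values above ``max_disparity`` are ignored.
    """
    disparity = getattr(pred, "disparity", pred)
    gt = np.asarray(gt, dtype=np.float32)
    if gt.ndim == 2:
        gt = gt[None]
    h, w = gt.shape[-2:]
    mask = np.ones(gt.shape, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    if mask.ndim == 2:
        mask = mask[None]
    mask = mask & (gt <= max_disparity)
    n = int(mask.sum())
    if n == 0:
        logger.warning("disparity loss: no valid pixels in batch, returning 0")
        return Tensor(0.0)
    gt_t = Tensor(gt[:, None])
    mask_t = Tensor(mask[:, None].astype(np.float32))
    per_scale = []
    for scale in sorted(disparity):
        p = as_tensor(disparity[scale])
        ratio = float(2 ** (scale - 1))
        if p.data.shape[-2:] != (h, w):
            p = ops.bilinear_resize(p, (h, w))
        p = p * ratio if ratio != 1.0 else p
        err = smooth_l1(gt_t - p) * mask_t
        per_scale.append(err.sum() * (1.0 / n))
    total = per_scale[0]
    for t in per_scale[1:]:
        total = total + t
    return total * (1.0 / len(per_scale))


def wbce(s, s_hat, beta: float) -> Tensor:
    """Weighted binary cross-entropy, normalized by pixel count.

    Foreground terms are weighted by ``beta``; predicted probabilities are
    clipped away from {0, 1} before the logarithms.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    s = _img(np.asarray(s, dtype=np.float32)) if not isinstance(s, Tensor) else s
    s_hat = _img(s_hat) if not isinstance(s_hat, Tensor) else s_hat
    p = s_hat.clip(1e-7, 1.0 - 1e-7)
    term = beta * s * p.log() + (1.0 - s) * (1.0 - p).log()
    return -term.mean()


def soft_dice_loss(s, s_hat, eps: float = 1e-5) -> Tensor:
    """1 - (2 * intersection + eps) / (|s| + |s_hat| + eps)."""
    s = _img(np.asarray(s, dtype=np.float32)) if not isinstance(s, Tensor) else s
    s_hat = _img(s_hat) if not isinstance(s_hat, Tensor) else s_hat
    inter = (s * s_hat).sum()
    total = s.sum() + s_hat.sum()
    return 1.0 - (2.0 * inter + eps) / (total + eps)


def segmentation_loss(s, s_hat, weights: LossWeights | None = None) -> Tensor:
    weights = weights or LossWeights()
    return 0.5 * wbce(s, s_hat, weights.beta_wbce) \
        + 0.5 * soft_dice_loss(s, s_hat, weights.dice_eps)


def ssim_loss(image, reconstruction, window: int = 11,
              c1: float = 0.01 ** 2, c2: float = 0.03 ** 2) -> Tensor:
    """(1 - mean SSIM) / 2 over uniform window x window patches per channel."""
    u = _img(image)
    v = _img(reconstruction)
    h, w = u.data.shape[-2:]
    if window > h or window > w:
        raise ValueError(f"SSIM window {window} exceeds image size {(h, w)}")
    mu_u = ops.box_mean(u, window)
    mu_v = ops.box_mean(v, window)
    var_u = ops.box_mean(u * u, window) - mu_u * mu_u
    var_v = ops.box_mean(v * v, window) - mu_v * mu_v
    cov = ops.box_mean(u * v, window) - mu_u * mu_v
    num = (2.0 * mu_u * mu_v + c1) * (2.0 * cov + c2)
    den = (mu_u * mu_u + mu_v * mu_v + c1) * (var_u + var_v + c2)
    ssim_m = (num / den).mean()
    return (1.0 - ssim_m) * 0.5


def photometric_loss(image, reconstruction) -> Tensor:
    """Mean smooth-L1 between the left image and its reconstruction.

    Occluded regions are not excluded: the reconstruction cannot match
    there even under perfect disparity, which is accepted by design.
    """
    return smooth_l1(_img(image) - _img(reconstruction)).mean()


def smoothness_loss(image, disparity, max_disparity: float = 320.0) -> Tensor:
    """Edge-aware first-order smoothness of the normalized disparity.

    Disparity is divided by the search range so both factors live on the
    image intensity scale; gradients are forward differences, and the image
    edge strength is the mean absolute channel gradient.
    """
    img = _img(image)
    d = as_tensor(disparity)
    if d.data.ndim == 2:
        d = d.reshape(1, 1, *d.data.shape)
    dn = d * (1.0 / max_disparity)
    dx = (dn[..., :, 1:] - dn[..., :, :-1]).abs()
    dy = (dn[..., 1:, :] - dn[..., :-1, :]).abs()
    ix = (img[..., :, 1:] - img[..., :, :-1]).abs().mean(axis=1, keepdims=True)
    iy = (img[..., 1:, :] - img[..., :-1, :]).abs().mean(axis=1, keepdims=True)
    return (dx * (-ix).exp()).mean() + (dy * (-iy).exp()).mean()


def self_supervised_disparity_loss(left, right, disparity_s1,
                                   weights: LossWeights | None = None) -> Tensor:
    """Photometric + SSIM reconstruction terms plus edge-aware smoothness.

    beta_ss * (alpha_ss * photometric + (1 - alpha_ss) * ssim)
    + (1 - beta_ss) * smoothness, computed on the full-resolution output.
    """
    weights = weights or LossWeights()
    left_t = _img(left)
    right_t = _img(right)
    d = as_tensor(disparity_s1)
    if d.data.ndim == 2:
        d = d.reshape(1, 1, *d.data.shape)
    recon = ops.warp_horizontal(right_t, d)
    ph = photometric_loss(left_t, recon)
    ss = ssim_loss(left_t, recon, weights.ssim_window, weights.ssim_c1, weights.ssim_c2)
    sm = smoothness_loss(left_t, d, weights.max_disparity)
    return weights.beta_ss * (weights.alpha_ss * ph + (1.0 - weights.alpha_ss) * ss) \
        + (1.0 - weights.beta_ss) * sm


def multitask_loss(ss_disp_value, seg_value, alpha_mt: float = 0.2) -> Tensor:
    """alpha_mt * self-supervised disparity + (1 - alpha_mt) * segmentation."""
    return alpha_mt * as_tensor(ss_disp_value) + (1.0 - alpha_mt) * as_tensor(seg_value)
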