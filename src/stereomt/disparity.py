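"""Cascaded cost-volume disparity head with full-resolution refinement.

Disparity is estimated coarse-to-fine over the encoder pyramid.  At the
coarsest scale S6 a unidirectional cost volume over offsets 0..D_max/32
seeds the cascade; at each finer scale the previous estimate is bilinearly
up-sampled, passed through a learned up-scaling convolution (initialized to
approximate a plain x2), used to pre-align the right features, and a shallow
bidirectional cost volume over offsets -2..+2 drives a convolutional tower
that regresses a residual correction.  At full resolution no cost volume is
built (tolerating ~2 px of vertical rectification error); instead a 2-D
hourglass refines the up-scaled S2 estimate as a residual.

Matching costs are the mean over channels of the element-wise product of
left features and (aligned) right features, keeping activations small; out
of image samples contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, as_tensor, concat, ops
from .encoder import FeaturePyramid, VARIANT_WIDTHS, _to_nchw

__all__ = [
    "CostVolume", "DisparityPyramid", "warp_right_to_left", "build_cost_volume",
    "MatchingModule", "Hourglass", "DisparityHead",
    "cost_volume_planes", "TOWER_WIDTHS", "HOURGLASS_WIDTHS",
]

TOWER_WIDTHS = {
    "lightweight": (128, 128, 96, 64, 32),
    "resnet34": (128, 128, 96, 64, 32),
    "tiny": (32, 32, 24, 16, 8),
}

HOURGLASS_WIDTHS = {
    "lightweight": (16, 32, 64),
    "resnet34": (16, 32, 64),
    "tiny": (8, 12, 16),
}


def cost_volume_planes(max_disparity: float, scale_factor: int = 32) -> int:
    """Plane count of the coarsest (unidirectional) cost volume.

    One plane per integer offset from zero to max_disparity / scale_factor.
    """
    return int(max_disparity) // scale_factor + 1


@dataclass
class CostVolume:
    """Matching-cost planes (N, D, H, W) plus the offset convention."""

    costs: Tensor
    offsets: tuple[int, ...]


@dataclass
class DisparityPyramid:
    """Disparity maps per scale; values are pixels at each scale's resolution."""

    disparity: dict[int, Tensor]

    def __getitem__(self, scale: int) -> Tensor:
        return self.disparity[scale]

    def scales(self):
        return sorted(self.disparity)

    def full_resolution(self) -> np.ndarray:
        """The deployment output: the S1 map as an (H, W) array."""
        return self.disparity[1].data[0, 0]


def warp_right_to_left(source, disparity) -> Tensor:
    """Differentiable horizontal warp: out(x, y, c) = source(x - d(x, y), y, c).

    Accepts (H, W, C) arrays or NCHW tensors; out-of-image samples are zero.
    """
    src = source
    if not isinstance(src, Tensor):
        arr = np.asarray(src, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[..., None]
        src = Tensor(arr.transpose(2, 0, 1)[None])
        d = np.asarray(disparity, dtype=np.float32)
        dt = disparity if isinstance(disparity, Tensor) else Tensor(d[None, None])
        out = ops.warp_horizontal(src, dt)
        res = out.data[0].transpose(1, 2, 0)
        return res[..., 0] if np.asarray(source).ndim == 2 else res
    return ops.warp_horizontal(src, as_tensor(disparity))


def _shift_columns(x: Tensor, offset: int) -> Tensor:
    """shifted(x_col) = x(x_col - offset), zero outside the image."""
    if offset == 0:
        return x
    w = x.data.shape[-1]
    if abs(offset) >= w:
        return Tensor(np.zeros_like(x.data))
    if offset > 0:
        return x[..., : w - offset].pad2d(0, 0, offset, 0)
    return x[..., -offset:].pad2d(0, 0, 0, -offset)


def build_cost_volume(left_feat, right_feat_aligned, offsets) -> CostVolume:
    """Shallow cost volume: per-offset mean over channels of feature products."""
    offsets = tuple(int(o) for o in offsets)
    if not offsets:
        raise ValueError("offset list must not be empty")
    if list(offsets) != sorted(offsets):
        raise ValueError("offsets must be sorted ascending")
    lf = _as_feat(left_feat)
    rf = _as_feat(right_feat_aligned)
    if lf.data.shape != rf.data.shape:
        raise ValueError(f"feature shape mismatch {lf.data.shape} vs {rf.data.shape}")
    planes = [(lf * _shift_columns(rf, o)).mean(axis=1, keepdims=True) for o in offsets]
    return CostVolume(concat(planes, axis=1), offsets)


def _as_feat(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 3:  # H, W, C
        arr = arr.transpose(2, 0, 1)[None]
    return Tensor(arr)


class _UpscaleConv(nn.Module):
    """Single 3x3 conv applied to the x2-up-sampled previous disparity.

    Doubles the disparity values (the resolution doubles) while smoothing
    interpolation artifacts; initialized as an exact x2 centre tap so the
    cascade starts from plain up-sampling.
    """

    def __init__(self):
        super().__init__()
        self.conv = nn.Conv2d(1, 1, 3, stride=1, padding=1, bias=True)
        self.conv.weight.data[:] = 0.0
        self.conv.weight.data[0, 0, 1, 1] = 2.0
        self.conv.bias.data[:] = 0.0

    def forward(self, x):
        return self.conv(x)


def _tower(cin: int, widths) -> nn.Sequential:
    layers = []
    for w in widths:
        layers += [nn.Conv2d(cin, w, 3, 1, 1, bias=False),
                   nn.BatchNorm2d(w), nn.LeakyReLU(0.1)]
        cin = w
    layers.append(nn.Conv2d(cin, 1, 3, 1, 1, bias=True))  # bare disparity regressor
    return nn.Sequential(*layers)


class MatchingModule(nn.Module):
    """Per-scale warp -> shallow cost volume -> residual refinement."""

    def __init__(self, feat_ch: int, tower_widths, coarsest: bool = False,
                 n_coarse_planes: int = 11):
        super().__init__()
        self.coarsest = coarsest
        if coarsest:
            self.offsets = tuple(range(n_coarse_planes))
        else:
            self.offsets = (-2, -1, 0, 1, 2)
            self.upscale = _UpscaleConv()
        self.tower = _tower(feat_ch + len(self.offsets), tower_widths)

    def forward(self, left_feat: Tensor, right_feat: Tensor,
                disparity_prev: Tensor | None = None) -> Tensor:
        if self.coarsest:
            if disparity_prev is not None:
                raise ValueError("coarsest scale takes no previous disparity")
            volume = build_cost_volume(left_feat, right_feat, self.offsets)
            return self.tower(concat([volume.costs, left_feat], axis=1))
        if disparity_prev is None:
            raise ValueError("non-coarsest scale requires the previous disparity")
        up = self.upscale(ops.upsample2x(disparity_prev))
        aligned = ops.warp_horizontal(right_feat, up)
        volume = build_cost_volume(left_feat, aligned, self.offsets)
        residual = self.tower(concat([volume.costs, left_feat], axis=1))
        return residual + up


class Hourglass(nn.Module):
    """2-D encoder-decoder residual refiner at full resolution.

    Input is the up-scaled disparity concatenated with the left image; two
    stride-2 stages down, two transposed-conv stages up with skip fusion,
    then a bare conv regresses the residual.
    """

    def __init__(self, widths=(16, 32, 64), in_ch: int = 4):
        super().__init__()
        w0, w1, w2 = widths
        self.pre = _conv_block(in_ch, w0, 1)
        self.down1 = _conv_block(w0, w1, 2)
        self.down2 = _conv_block(w1, w2, 2)
        self.up1 = nn.ConvTranspose2d(w2, w1, 4, 2, 1)
        self.fuse1 = _conv_block(2 * w1, w1, 1)
        self.up2 = nn.ConvTranspose2d(w1, w0, 4, 2, 1)
        self.fuse2 = _conv_block(2 * w0, w0, 1)
        self.out = nn.Conv2d(w0, 1, 3, 1, 1, bias=True)

    def forward(self, x):
        e0 = self.pre(x)
        e1 = self.down1(e0)
        e2 = self.down2(e1)
        d1 = self.fuse1(concat([self.up1(e2), e1], axis=1))
        d0 = self.fuse2(concat([self.up2(d1), e0], axis=1))
        return self.out(d0)


def _conv_block(cin, cout, stride):
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, stride, 1, bias=False),
        nn.BatchNorm2d(cout),
        nn.LeakyReLU(0.1),
    )


class DisparityHead(nn.Module):
    """Full cascade S6 -> S2 plus the S1 hourglass refinement stage."""

    def __init__(self, variant: str = "lightweight", max_disparity: float = 320.0):
        super().__init__()
        self.variant = variant
        self.max_disparity = float(max_disparity)
        widths = VARIANT_WIDTHS[variant]
        tower = TOWER_WIDTHS[variant]
        n_planes = cost_volume_planes(max_disparity)
        self.match6 = MatchingModule(widths[4], tower, coarsest=True,
                                     n_coarse_planes=n_planes)
        self.match5 = MatchingModule(widths[3], tower)
        self.match4 = MatchingModule(widths[2], tower)
        self.match3 = MatchingModule(widths[1], tower)
        self.match2 = MatchingModule(widths[0], tower)
        self.upscale_s1 = _UpscaleConv()
        self.hourglass = Hourglass(HOURGLASS_WIDTHS[variant], in_ch=4)

    def estimate_scale(self, scale: int, left_feat, right_feat,
                       disparity_prev=None) -> Tensor:
        module = getattr(self, f"match{scale}")
        return module(_as_feat(left_feat), _as_feat(right_feat),
                      None if disparity_prev is None else as_tensor(disparity_prev))

    def refine_full_res(self, disparity_s2: Tensor, left_image) -> Tensor:
        left = _to_nchw(left_image)
        up = self.upscale_s1(ops.upsample2x(as_tensor(disparity_s2)))
        residual = self.hourglass(concat([up, left], axis=1))
        return up + residual

    def forward(self, left_pyramid: FeaturePyramid, right_pyramid: FeaturePyramid,
                left_image, cascade_noise_px: float = 0.0,
                noise_rng: np.random.Generator | None = None) -> DisparityPyramid:
        """Run the cascade S6 -> S1.

        ``cascade_noise_px`` (training only) perturbs each scale's incoming
        estimate with a random per-sample offset before pre-alignment, so
        the residual towers keep seeing the full correction range instead
        of only the shrinking residuals of a converging cascade; the clean
        supervised loss then teaches them to undo such errors.
        """
        if left_pyramid.variant != right_pyramid.variant:
            raise ValueError(
                f"pyramid variant mismatch: {left_pyramid.variant} vs {right_pyramid.variant}"
            )
        inject = cascade_noise_px > 0 and self.training
        if inject and noise_rng is None:
            noise_rng = np.random.default_rng(0)
        d = {}
        d[6] = self.match6(left_pyramid[6], right_pyramid[6])
        for scale in (5, 4, 3, 2):
            prev = d[scale + 1]
            if inject:
                n = prev.data.shape[0]
                eps = noise_rng.uniform(-cascade_noise_px, cascade_noise_px,
                                        size=(n, 1, 1, 1)).astype(np.float32)
                prev = prev + Tensor(eps)
            d[scale] = getattr(self, f"match{scale}")(
                left_pyramid[scale], right_pyramid[scale], prev
            )
        d[1] = self.refine_full_res(d[2], left_image)
        return DisparityPyramid(d)
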