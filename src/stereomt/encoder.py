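"""Shared five-scale feature encoders feeding both task heads.

Two variants produce feature pyramids at scales S2..S6 (resolutions /2 to
/32 of the input):

* ``lightweight`` — five down-sampling blocks of two 3x3 convolutions
  (stride 2 then stride 1), each followed by batch norm and LeakyReLU(0.1),
  with widths 16, 32, 64, 96, 128.  Convolutions preceding batch norm carry
  no bias (redundant with the batch-norm shift).
* ``resnet34`` — a headless ResNet-34: the /2 stem output (before the
  max-pool) and the outputs of the four residual stages give widths
  64, 64, 128, 256, 512 at the same five scales.

A ``tiny`` width-reduced sibling of the lightweight encoder is provided for
CPU-scale experiments and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "VARIANT_WIDTHS", "FeaturePyramid", "LightweightEncoder", "ResNet34Encoder",
    "build_encoder", "extract_pyramid", "count_parameters", "SCALES",
]

SCALES = (2, 3, 4, 5, 6)

VARIANT_WIDTHS = {
    "lightweight": (16, 32, 64, 96, 128),
    "resnet34": (64, 64, 128, 256, 512),
    "tiny": (8, 12, 16, 20, 24),
}


@dataclass
class FeaturePyramid:
    """Per-scale feature maps S2..S6 as NCHW tensors."""

    features: dict[int, Tensor]
    variant: str

    def __getitem__(self, scale: int) -> Tensor:
        return self.features[scale]

    def scales(self):
        return sorted(self.features)


def _check_input(x: np.ndarray | Tensor):
    h, w = (x.data if isinstance(x, Tensor) else x).shape[-2:]
    if h % 32:
        raise ValueError(f"input height {h} not divisible by 32")
    if w % 32:
        raise ValueError(f"input width {w} not divisible by 32")


def _to_nchw(image) -> Tensor:
    """Accept (H, W, 3) or (N, 3, H, W); return NCHW tensor."""
    if isinstance(image, Tensor):
        return image
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[2] == 3:
        arr = arr.transpose(2, 0, 1)[None]
    elif arr.ndim != 4:
        raise ValueError(f"expected (H, W, 3) or (N, C, H, W) image, got {arr.shape}")
    return Tensor(arr)


def _conv_bn_lrelu(cin, cout, stride):
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False),
        nn.BatchNorm2d(cout),
        nn.LeakyReLU(0.1),
    )


class LightweightEncoder(nn.Module):
    """Pyramidal encoder of five stride-2 double-conv blocks."""

    def __init__(self, widths=VARIANT_WIDTHS["lightweight"], variant="lightweight"):
        super().__init__()
        self.variant = variant
        self.widths = tuple(widths)
        cin = 3
        self.blocks = []
        for k, w in enumerate(widths):
            block = nn.Sequential(
                nn.Conv2d(cin, w, 3, stride=2, padding=1, bias=False),
                nn.BatchNorm2d(w),
                nn.LeakyReLU(0.1),
                nn.Conv2d(w, w, 3, stride=1, padding=1, bias=False),
                nn.BatchNorm2d(w),
                nn.LeakyReLU(0.1),
            )
            setattr(self, f"block{k + 2}", block)
            self.blocks.append(block)
            cin = w

    def forward(self, image) -> FeaturePyramid:
        x = _to_nchw(image)
        _check_input(x)
        feats = {}
        for scale, block in zip(SCALES, self.blocks):
            x = block(x)
            feats[scale] = x
        return FeaturePyramid(feats, self.variant)


class _BasicBlock(nn.Module):
    def __init__(self, cin, cout, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, stride=1, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=stride, padding=0, bias=False)
            self.down_bn = nn.BatchNorm2d(cout)
            self.has_down = True
        else:
            self.has_down = False

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = self.down_bn(self.down_conv(x)) if self.has_down else x
        return (out + skip).relu()


class ResNet34Encoder(nn.Module):
    """Headless ResNet-34 tapped at /2, /4, /8, /16 and /32.

    Stage layout (3, 4, 6, 3) basic blocks at widths 64, 128, 256, 512; the
    /2 tap is the stem conv output before the max-pool, the /4 tap the first
    stage after it.
    """

    variant = "resnet34"
    widths = VARIANT_WIDTHS["resnet34"]

    def __init__(self):
        super().__init__()
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(64)
        self.pool = nn.MaxPool2d(3, 2, 1)
        layout = ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2))
        cin = 64
        self.stages = []
        for s, (w, n_blocks, stride) in enumerate(layout, start=1):
            blocks = [_BasicBlock(cin, w, stride)]
            blocks += [_BasicBlock(w, w, 1) for _ in range(n_blocks - 1)]
            stage = nn.Sequential(*blocks)
            setattr(self, f"stage{s}", stage)
            self.stages.append(stage)
            cin = w

    def forward(self, image) -> FeaturePyramid:
        x = _to_nchw(image)
        _check_input(x)
        s2 = self.stem_bn(self.stem_conv(x)).relu()
        x = self.pool(s2)
        feats = {2: s2}
        for scale, stage in zip((3, 4, 5, 6), self.stages):
            x = stage(x)
            feats[scale] = x
        return FeaturePyramid(feats, self.variant)


def build_encoder(variant: str) -> nn.Module:
    if variant == "lightweight":
        return LightweightEncoder()
    if variant == "tiny":
        return LightweightEncoder(VARIANT_WIDTHS["tiny"], variant="tiny")
    if variant == "resnet34":
        return ResNet34Encoder()
    raise ValueError(f"unknown encoder variant '{variant}'")


def extract_pyramid(image, variant: str = "lightweight",
                    encoder: nn.Module | None = None) -> FeaturePyramid:
    """Run an encoder over a normalized image and return the S2..S6 pyramid."""
    enc = encoder if encoder is not None else build_encoder(variant)
    return enc(image)


def count_parameters(variant: str, scope: str = "encoder",
                     max_disparity: float = 320.0) -> int:
    """Number of trainable scalar parameters in the named model scope."""
    from .model import model_factory  # deferred: model depends on encoder

    if scope == "encoder":
        return build_encoder(variant).num_parameters()
    if scope == "disparity_head":
        m = model_factory(variant, heads={"disparity"}, max_disparity=max_disparity)
        return m.disparity_head.num_parameters()
    if scope == "segmentation_head":
        m = model_factory(variant, heads={"segmentation"}, max_disparity=max_disparity)
        return m.segmentation_head.num_parameters()
    if scope == "full_multitask":
        m = model_factory(variant, heads={"disparity", "segmentation"},
                          max_disparity=max_disparity)
        return m.num_parameters()
    raise ValueError(f"unknown scope '{scope}'")
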