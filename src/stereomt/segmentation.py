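"""U-Net-style decoder producing full-resolution binary instrument masks.

The decoder ascends the shared pyramid from S6 to S2.  Each stage
up-samples with a 4x4 stride-2 transposed convolution (so up-sampled maps
exactly match the skip-connection sizes), concatenates the encoder skip,
and applies two 3x3 convolutions each followed by batch norm and
LeakyReLU(0.1).  The S2 output is up-sampled once more and a single 3x3
convolution regresses the one-channel logits; probabilities are the sigmoid
of the logits and masks use a strict > 0.5 threshold by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat
from .encoder import FeaturePyramid, VARIANT_WIDTHS, SCALES

__all__ = ["SegmentationOutput", "SegmentationHead", "binarize"]


@dataclass
class SegmentationOutput:
    logits: np.ndarray      # (H, W)
    probability: np.ndarray  # (H, W) in [0, 1]
    mask: np.ndarray         # (H, W) bool
    logits_tensor: Tensor | None = None  # retained for loss backprop


def binarize(probability: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict greater-than thresholding; ties go to background."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return np.asarray(probability) > threshold


def _double_conv(cin, cout):
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, 1, 1, bias=False),
        nn.BatchNorm2d(cout),
        nn.LeakyReLU(0.1),
        nn.Conv2d(cout, cout, 3, 1, 1, bias=False),
        nn.BatchNorm2d(cout),
        nn.LeakyReLU(0.1),
    )


class SegmentationHead(nn.Module):
    """Decoder stage widths mirror the active encoder's widths per scale."""

    def __init__(self, variant: str = "lightweight", threshold: float = 0.5):
        super().__init__()
        self.variant = variant
        self.threshold = threshold
        w = VARIANT_WIDTHS[variant]  # widths at S2..S6
        # stages S5..S2: upsample previous decoder output, concat skip, refine
        cin = w[4]
        for scale in (5, 4, 3, 2):
            skip_ch = w[scale - 2]
            up = nn.ConvTranspose2d(cin, skip_ch, 4, 2, 1)
            fuse = _double_conv(2 * skip_ch, skip_ch)
            setattr(self, f"up{scale}", up)
            setattr(self, f"fuse{scale}", fuse)
            cin = skip_ch
        self.up1 = nn.ConvTranspose2d(w[0], w[0], 4, 2, 1)
        self.out = nn.Conv2d(w[0], 1, 3, 1, 1, bias=True)

    def decode_logits(self, pyramid: FeaturePyramid) -> Tensor:
        missing = [s for s in SCALES if s not in pyramid.features]
        if missing:
            raise ValueError(f"pyramid missing scale(s) {missing}")
        x = pyramid[6]
        for scale in (5, 4, 3, 2):
            up = getattr(self, f"up{scale}")(x)
            x = getattr(self, f"fuse{scale}")(concat([up, pyramid[scale]], axis=1))
        return self.out(self.up1(x))

    def forward(self, pyramid: FeaturePyramid) -> SegmentationOutput:
        logits = self.decode_logits(pyramid)
        prob_t = logits.sigmoid()
        logits_np = logits.data[0, 0]
        prob = prob_t.data[0, 0]
        return SegmentationOutput(
            logits=logits_np,
            probability=prob,
            mask=binarize(prob, self.threshold),
            logits_tensor=logits,
        )

    decode_mask = forward
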