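"""Model assembly: shared encoder plus any subset of task heads.

Single-head and multi-task models share the encoder parameter layout, so
checkpoints interchange between them; loading a disparity-only checkpoint
into a multi-task model leaves the segmentation head at its initialization.
"""

from __future__ import annotations

import json

import numpy as np

from . import nn
from .encoder import build_encoder, FeaturePyramid
from .disparity import DisparityHead, DisparityPyramid
from .segmentation import SegmentationHead, SegmentationOutput

__all__ = ["MultiTaskModel", "model_factory", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT_VERSION = 1


class MultiTaskModel(nn.Module):
    """Encoder + optional disparity and segmentation heads.

    The encoder runs once per view; in multi-task mode the left features
    feed both heads.
    """

    def __init__(self, variant: str, heads: set[str], max_disparity: float = 320.0):
        super().__init__()
        heads = set(heads)
        unknown = heads - {"disparity", "segmentation"}
        if unknown:
            raise ValueError(f"unknown heads {sorted(unknown)}")
        if not heads:
            raise ValueError("at least one head is required")
        self.variant = variant
        self.heads = heads
        self.max_disparity = float(max_disparity)
        self.encoder = build_encoder(variant)
        self.encoder_calls = 0  # instrumentation for the sharing contract
        if "disparity" in heads:
            self.disparity_head = DisparityHead(variant, max_disparity)
        if "segmentation" in heads:
            self.segmentation_head = SegmentationHead(variant)

    def encode(self, image) -> FeaturePyramid:
        self.encoder_calls += 1
        return self.encoder(image)

    def forward(self, left, right=None) -> dict:
        """Run the requested heads; ``right`` is only needed for disparity."""
        out: dict = {}
        left_pyr = self.encode(left)
        if "disparity" in self.heads:
            if right is None:
                raise ValueError("disparity estimation requires the right image")
            right_pyr = self.encode(right)
            out["disparity"] = self.disparity_head(left_pyr, right_pyr, left)
        if "segmentation" in self.heads:
            out["segmentation"] = self.segmentation_head(left_pyr)
        return out

    def predict_disparity(self, left, right) -> DisparityPyramid:
        return self.forward(left, right)["disparity"]

    def predict_mask(self, left) -> SegmentationOutput:
        pyr = self.encode(left)
        return self.segmentation_head(pyr)


def model_factory(variant: str, heads=("disparity", "segmentation"),
                  max_disparity: float = 320.0, seed: int | None = None) -> MultiTaskModel:
    """Construct a model; ``seed`` fixes the weight initialization stream."""
    if seed is not None:
        nn.seed_init(seed)
    return MultiTaskModel(variant, set(heads), max_disparity)


def save_checkpoint(model: MultiTaskModel, path) -> None:
    meta = {
        "variant": model.variant,
        "heads": sorted(model.heads),
        "max_disparity": model.max_disparity,
        "format_version": CHECKPOINT_FORMAT_VERSION,
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path, model: MultiTaskModel, allow_partial: bool = True) -> None:
    """Load a flat named-parameter archive; variant tags must match."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"checkpoint format {meta.get('format_version')} unsupported "
                f"(expected {CHECKPOINT_FORMAT_VERSION})"
            )
        if meta["variant"] != model.variant:
            raise ValueError(
                f"checkpoint variant '{meta['variant']}' does not match model "
                f"variant '{model.variant}'"
            )
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    if allow_partial:
        own = dict(model.named_parameters())
        own.update(dict(model.named_buffers()))
        state = {k: v for k, v in state.items() if k in own}
        model.load_state_dict(state, strict=False)
    else:
        model.load_state_dict(state, strict=True)
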