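"""Evaluation metrics: EPE, Bad3, depth MAE, IoU, and the coverage filter.

Disparity metrics are computed over a validity mask; depth follows the
rectified-stereo relation depth = focal * baseline / disparity, with
near-zero disparities marked invalid to cap the depth blow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraRig", "epe", "bad3", "disparity_to_depth", "depth_mae", "iou",
    "coverage_filter",
]


@dataclass(frozen=True)
class CameraRig:
    """Rectified-stereo intrinsics needed for depth conversion."""

    focal_px: float
    baseline_mm: float

    def __post_init__(self):
        if self.focal_px <= 0 or self.baseline_mm <= 0:
            raise ValueError("focal_px and baseline_mm must be strictly positive")


def _masked(pred, gt, valid):
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    mask = np.ones(gt.shape, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    if not mask.any():
        raise ValueError("metric undefined: no valid pixels")
    return pred[mask], gt[mask]


def epe(pred, gt, valid=None) -> float:
    """End-point error: mean absolute disparity difference in pixels."""
    p, g = _masked(pred, gt, valid)
    return float(np.mean(np.abs(p - g)))


def bad3(pred, gt, valid=None, threshold: float = 3.0) -> float:
    """Percentage of valid pixels whose error strictly exceeds ``threshold``."""
    p, g = _masked(pred, gt, valid)
    return float(100.0 * np.mean(np.abs(p - g) > threshold))


def disparity_to_depth(disparity, rig: CameraRig,
                       d_floor: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Depth in mm plus a validity mask.

    Disparities at or below ``d_floor`` (default 0.5 px) are marked invalid
    rather than converted: near-zero disparities map to unbounded depths.
    """
    d = np.asarray(disparity, dtype=np.float64)
    valid = d > d_floor
    depth = np.zeros_like(d)
    np.divide(rig.focal_px * rig.baseline_mm, d, out=depth, where=valid)
    return depth, valid


def depth_mae(pred_depth, gt_depth, valid=None) -> float:
    """Mean absolute depth error in millimetres over jointly valid pixels."""
    p, g = _masked(pred_depth, gt_depth, valid)
    return float(np.mean(np.abs(p - g)))


def iou(pred_mask, gt_mask) -> float:
    """Jaccard index; two empty masks agree perfectly (1.0)."""
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(gt_mask, dtype=bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shape mismatch {p.shape} vs {g.shape}")
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def coverage_filter(gt_valid, threshold_fraction: float = 0.10) -> bool:
    """True iff the valid ground-truth fraction strictly exceeds the threshold.

    Frames failing the filter are excluded from aggregate evaluation.
    """
    mask = np.asarray(gt_valid, dtype=bool)
    if mask.size == 0:
        return False
    return bool(mask.mean() > threshold_fraction)
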