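"""Synthetic rectified stereo scenes with exactly known disparity.

Real endoscopic stereo ground truth is expensive (structured light or CT
registration); these generators instead build scenes where the disparity
field is known by construction, so the matching network, the losses and the
metrics can all be exercised end to end.  Three generators are provided:

* fronto-parallel scenes — a single constant horizontal shift, the simplest
  verifiable stereo fixture;
* smooth scenes — a band-limited disparity field (sum of Gaussian bumps)
  with sub-pixel structure, occlusion-aware validity;
* instrument masks — elongated border-entering capsules emulating the
  class-balance statistic of surgical tool annotations (about 15 % of the
  frame covered on average).

The rectification contract throughout: a scene point seen at left pixel
(x, y) appears at right pixel (x - d(x, y), y), with d >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, label

__all__ = [
    "MAX_DISPARITY",
    "StereoSample",
    "generate_fronto_scene",
    "generate_smooth_scene",
    "generate_instrument_mask",
    "warp_right_to_left_numpy",
]

#: Largest disparity the matching head is configured to regress, in pixels.
MAX_DISPARITY = 320.0

# Texture octaves: (sigma, weight) of Gaussian-smoothed noise layers summed
# into a 1/f-like spectrum.  Pure white noise aliases under sub-pixel
# resampling and carries no low-frequency energy, which would leave the
# coarse pyramid scales with nothing to match; natural scenes do not look
# like that.
_TEXTURE_OCTAVES = ((1.2, 0.45), (4.0, 0.35), (12.0, 0.20))


@dataclass
class StereoSample:
    """A rectified stereo pair with optional dense annotations.

    left, right : (H, W, 3) float32 intensities in [0, 1]
    disparity   : (H, W) float32 pixels, or None
    valid       : (H, W) bool, or None — pixels with a usable correspondence
    mask        : (H, W) bool, or None — instrument foreground
    """

    left: np.ndarray
    right: np.ndarray
    disparity: np.ndarray | None = None
    valid: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.left.shape != self.right.shape:
            raise ValueError("left/right shape mismatch")
        h, w = self.left.shape[:2]
        for name in ("disparity", "valid", "mask"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (h, w):
                raise ValueError(f"{name} shape {arr.shape} != image {(h, w)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape[:2]


def _check_dims(height: int, width: int):
    if height % 32 or width % 32:
        raise ValueError(
            f"image size ({height}, {width}) must be divisible by 32 for the pyramid"
        )


def _texture(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    tex = np.zeros((height, width, 3))
    for sigma, weight in _TEXTURE_OCTAVES:
        layer = rng.uniform(0.0, 1.0, size=(height, width, 3))
        for c in range(3):
            layer[..., c] = gaussian_filter(layer[..., c], sigma, mode="nearest")
        # rescale each octave to unit peak-to-peak before weighting
        lo, hi = layer.min(), layer.max()
        tex += weight * (layer - lo) / max(hi - lo, 1e-8)
    lo, hi = tex.min(), tex.max()
    tex = 0.05 + 0.9 * (tex - lo) / max(hi - lo, 1e-8)
    return tex.astype(np.float32)


def _sample_columns(img: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinearly sample (H, W, C) at fractional columns, per row."""
    h, w = img.shape[:2]
    c0 = np.floor(cols).astype(int)
    f = (cols - c0)[..., None].astype(np.float32)
    c0 = np.clip(c0, 0, w - 1)
    c1 = np.clip(c0 + 1, 0, w - 1)
    rows = np.arange(h)[:, None]
    return (1.0 - f) * img[rows, c0] + f * img[rows, c1]


def warp_right_to_left_numpy(right: np.ndarray, disparity: np.ndarray) -> np.ndarray:
    """Reconstruct the left view: out(x, y) = right(x - d(x, y), y).

    Plain NumPy counterpart of the differentiable sampler, used for
    generator round-trip checks.  Out-of-image samples read as zero.
    """
    h, w = right.shape[:2]
    src = np.arange(w, dtype=np.float32)[None, :] - disparity
    out = _sample_columns(right, src)
    inside = ((src >= 0) & (src <= w - 1))[..., None]
    return (out * inside).astype(np.float32)


def generate_fronto_scene(height: int, width: int, shift: float, seed: int) -> StereoSample:
    """Constant-disparity scene: a fronto-parallel textured plane.

    The right view is the left texture resampled ``shift`` pixels to the
    right; the leftmost ``ceil(shift)`` columns of the left image have no
    right-image correspondence and are marked invalid.
    """
    _check_dims(height, width)
    # cap at half the width so a majority of columns keep a correspondence
    if not 0 <= shift <= min(MAX_DISPARITY, width / 2):
        raise ValueError(
            f"shift {shift} outside [0, {min(MAX_DISPARITY, width / 2)}]"
        )
    rng = np.random.default_rng(seed)
    pad = int(np.ceil(shift)) + 1
    tex = _texture(rng, height, width + pad)
    left = tex[:, :width].copy()
    cols = np.arange(width, dtype=np.float32)[None, :] + np.float32(shift)
    right = _sample_columns(tex, np.broadcast_to(cols, (height, width))).astype(np.float32)
    disparity = np.full((height, width), shift, dtype=np.float32)
    valid = np.ones((height, width), dtype=bool)
    valid[:, : int(np.ceil(shift))] = False
    return StereoSample(left=left, right=right, disparity=disparity, valid=valid)


def _invert_horizontal_map(disp_ext: np.ndarray, width: int, iters: int = 25) -> np.ndarray:
    """Solve x - d(x) = u for x, per right-image column u.

    ``disp_ext`` is the disparity field on an extended left grid (so the
    fixed point can run past the left image's right edge).  Requires
    |dd/dx| < 1, which the bump amplitudes guarantee; the iteration
    x <- u + d(x) is then a contraction.
    """
    h, w_ext = disp_ext.shape
    u = np.arange(width, dtype=np.float32)[None, :]
    x = np.broadcast_to(u, (h, width)).astype(np.float32).copy()
    for _ in range(iters):
        d_at_x = _sample_columns(disp_ext[..., None], x)[..., 0]
        x = u + d_at_x
    return x


def generate_smooth_scene(height: int, width: int, d_min: float, d_max: float,
                          seed: int, n_bumps: int = 6) -> StereoSample:
    """Scene with a smooth spatially varying disparity field.

    The field is a base level plus random 2-D Gaussian bumps, clipped to
    [d_min, d_max]; bump slopes are kept below 1 px/px so the left-to-right
    column map is invertible and the right view can be synthesized by exact
    horizontal resampling.  Validity excludes pixels whose right-image
    source column falls outside the frame and pixels occluded under a
    forward z-buffer over right-image columns (nearest disparity wins).
    """
    _check_dims(height, width)
    if not (0 <= d_min <= d_max <= MAX_DISPARITY):
        raise ValueError(f"disparity range [{d_min}, {d_max}] outside [0, {MAX_DISPARITY}]")
    rng = np.random.default_rng(seed)
    pad = int(np.ceil(d_max)) + 2
    w_ext = width + pad

    base = rng.uniform(d_min, d_max)
    field = np.full((height, w_ext), base, dtype=np.float64)
    yy, xx = np.mgrid[0:height, 0:w_ext].astype(np.float64)
    span = d_max - d_min
    if span > 0:
        for _ in range(n_bumps):
            cx = rng.uniform(0, w_ext)
            cy = rng.uniform(0, height)
            sigma = rng.uniform(0.15, 0.35) * min(height, width)
            # cap |slope| = |A| * exp(-1/2) / sigma below ~0.4 px/px
            max_amp = min(span, 0.4 * sigma / 0.6066)
            amp = rng.uniform(-max_amp, max_amp)
            field += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    field = np.clip(field, d_min, d_max)

    tex = _texture(rng, height, w_ext)
    left = tex[:, :width].copy()
    disparity = field[:, :width].astype(np.float32)

    x_of_u = _invert_horizontal_map(field.astype(np.float32), width)
    right = _sample_columns(tex, x_of_u).astype(np.float32)

    # validity: source column inside image, then z-buffer occlusion marking
    u = np.arange(width, dtype=np.float32)[None, :] - disparity
    valid = u >= 0
    bins = np.rint(u).astype(int)
    bins = np.clip(bins, 0, width - 1)
    order = np.argsort(disparity, axis=1)  # ascending: nearest (largest d) written last
    winner = np.full((height, width), -1, dtype=int)
    rows = np.arange(height)[:, None]
    winner[rows, bins[rows, order]] = order
    occluded = winner[rows, bins] != np.arange(width)[None, :]
    valid &= ~occluded
    return StereoSample(left=left, right=right, disparity=disparity, valid=valid)


def _capsule_mask(height: int, width: int, p0: np.ndarray, direction: np.ndarray,
                  length: float, radius: float) -> np.ndarray:
    """Rasterize a capsule (segment dilated by a disc) of given pose."""
    p1 = p0 + direction * length
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    px = xx - p0[0]
    py = yy - p0[1]
    seg = p1 - p0
    seg_len2 = float(seg @ seg) + 1e-12
    t = np.clip((px * seg[0] + py * seg[1]) / seg_len2, 0.0, 1.0)
    dx = px - t * seg[0]
    dy = py - t * seg[1]
    return dx * dx + dy * dy <= radius * radius


def generate_instrument_mask(height: int, width: int, n_tools: int, seed: int) -> np.ndarray:
    """Union of elongated tool-like capsules entering from the image border.

    Geometry (length/width distributions) was calibrated once so that two
    tools on a 256x320 frame cover on average about 15 % of the image, the
    class balance typical of surgical tool annotations.
    """
    if n_tools < 0:
        raise ValueError("n_tools must be >= 0")
    rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=bool)
    diag = float(np.hypot(height, width))
    for _ in range(n_tools):
        side = rng.integers(0, 4)  # 0=left 1=right 2=top 3=bottom
        if side == 0:
            p0 = np.array([0.0, rng.uniform(0, height)])
            normal = np.array([1.0, 0.0])
        elif side == 1:
            p0 = np.array([width - 1.0, rng.uniform(0, height)])
            normal = np.array([-1.0, 0.0])
        elif side == 2:
            p0 = np.array([rng.uniform(0, width), 0.0])
            normal = np.array([0.0, 1.0])
        else:
            p0 = np.array([rng.uniform(0, width), height - 1.0])
            normal = np.array([0.0, -1.0])
        angle = rng.uniform(-0.9, 0.9)
        cos, sin = np.cos(angle), np.sin(angle)
        direction = np.array([
            normal[0] * cos - normal[1] * sin,
            normal[0] * sin + normal[1] * cos,
        ])
        length = rng.uniform(0.40, 0.80) * diag
        radius = rng.uniform(0.048, 0.085) * min(height, width)
        mask |= _capsule_mask(height, width, p0, direction, length, radius)
    return mask


def components_touch_border(mask: np.ndarray) -> bool:
    """True iff every connected foreground component touches an image border."""
    labels, n = label(mask)
    if n == 0:
        return True
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border])) - {0}
    return border_labels == set(range(1, n + 1))
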