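"""Ground-truth disparity from 3-D points, plus image-conditioning steps.

Structured-light scanners deliver per-pixel 3-D points in the left camera
frame rather than disparities.  For a rectified rig the two projections of
a point share their row coordinate, so projecting each point into both
views and measuring the horizontal displacement of the column coordinates
yields the disparity directly.  Where several points land on the same left
pixel the nearest one (largest disparity) wins.

Also provided: de-interlacing by bilinear reconstruction of the odd rows,
and the black-border crop + bilinear resize used to condition interlaced
video frames before rectification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "RectifiedStereoRig", "points_to_disparity", "ProjectionReport",
    "deinterlace", "crop_and_resize",
]


@dataclass(frozen=True)
class RectifiedStereoRig:
    """Left/right 3x4 projection matrices of a rectified pair."""

    p_left: np.ndarray
    p_right: np.ndarray
    height: int
    width: int

    def __post_init__(self):
        for name in ("p_left", "p_right"):
            p = np.asarray(getattr(self, name), dtype=np.float64)
            if p.shape != (3, 4):
                raise ValueError(f"{name} must be 3x4, got {p.shape}")
            object.__setattr__(self, name, p)
        self._assert_rectified()

    @classmethod
    def from_intrinsics(cls, focal_px: float, cx: float, cy: float,
                        baseline_mm: float, height: int, width: int):
        """Canonical rectified rig: right camera displaced by the baseline
        along +x, identical intrinsics."""
        k = np.array([[focal_px, 0, cx], [0, focal_px, cy], [0, 0, 1.0]])
        p_left = k @ np.hstack([np.eye(3), np.zeros((3, 1))])
        t = np.array([[-baseline_mm], [0.0], [0.0]])
        p_right = k @ np.hstack([np.eye(3), t])
        return cls(p_left, p_right, height, width)

    def _assert_rectified(self, n_probe: int = 64, tol: float = 1e-9):
        rng = np.random.default_rng(0)
        pts = rng.uniform([-50, -50, 10], [50, 50, 300], size=(n_probe, 3))
        (_, yl, _), (_, yr, _) = (_project(self.p_left, pts), _project(self.p_right, pts))
        if np.max(np.abs(yl - yr)) > tol:
            raise ValueError("projection matrices are not rectified: row coordinates differ")


def _project(p: np.ndarray, points: np.ndarray):
    hom = np.hstack([points, np.ones((points.shape[0], 1))]) @ p.T
    z = hom[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = hom[:, 0] / z
        y = hom[:, 1] / z
    return x, y, z


@dataclass
class ProjectionReport:
    n_points: int
    n_dropped_behind: int
    n_dropped_outside: int
    n_collisions: int


def points_to_disparity(points: np.ndarray, rig: RectifiedStereoRig
                        ) -> tuple[np.ndarray, np.ndarray, ProjectionReport]:
    """Sparse disparity map from 3-D points via dual projection.

    Each point is projected into both rectified views; its disparity
    x_left - x_right is written at the rounded left-view pixel.  Points
    behind the camera or projecting outside the image are dropped; pixel
    collisions keep the largest disparity (the nearest point).
    Returns (disparity, validity, report).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError(f"points must be (N, 3), got {points.shape}")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    h, w = rig.height, rig.width
    xl, yl, zl = _project(rig.p_left, points)
    xr, _, zr = _project(rig.p_right, points)
    in_front = (zl > 0) & (zr > 0)
    col = np.rint(xl).astype(int)
    row = np.rint(yl).astype(int)
    inside = (col >= 0) & (col < w) & (row >= 0) & (row < h)
    keep = in_front & inside
    disp_vals = xl - xr
    disparity = np.zeros((h, w), dtype=np.float32)
    valid = np.zeros((h, w), dtype=bool)
    # nearest point wins: write in ascending disparity order so the largest lands last
    order = np.argsort(disp_vals[keep])
    rows, cols, vals = row[keep][order], col[keep][order], disp_vals[keep][order]
    disparity[rows, cols] = vals
    valid[rows, cols] = True
    n_collisions = int(len(vals) - valid.sum())
    report = ProjectionReport(
        n_points=len(points),
        n_dropped_behind=int((~in_front).sum()),
        n_dropped_outside=int((in_front & ~inside).sum()),
        n_collisions=n_collisions,
    )
    return disparity, valid, report


def deinterlace(image: np.ndarray) -> np.ndarray:
    """Replace odd rows by the bilinear mean of their even neighbours.

    Even rows are untouched and the output keeps the input size; the last
    odd row, lacking a lower neighbour, copies the row above.  The
    operation is idempotent.
    """
    img = np.asarray(image, dtype=np.float32)
    h = img.shape[0]
    if h % 2:
        raise ValueError(f"height {h} must be even for de-interlacing")
    out = img.copy()
    odd = np.arange(1, h, 2)
    upper = img[odd - 1]
    lower = img[np.minimum(odd + 1, h - 2)]
    out[odd] = 0.5 * (upper + lower)
    return out


def crop_and_resize(frame: np.ndarray, target: tuple[int, int] = (1280, 1024),
                    border_threshold: float = 8.0 / 255.0) -> np.ndarray:
    """Crop the black periphery and bilinearly resize to ``target`` (W, H).

    The content box is the tight bounding box of pixels whose luminance
    exceeds ``border_threshold`` (intensities in [0, 1]).
    """
    img = np.asarray(frame, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) frame, got {img.shape}")
    luma = img.mean(axis=2)
    content = luma > border_threshold
    if not content.any():
        raise ValueError("frame has no non-black content to crop")
    rows = np.flatnonzero(content.any(axis=1))
    cols = np.flatnonzero(content.any(axis=0))
    cropped = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    tw, th = target
    out = _sk_resize(cropped, (th, tw, 3), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)
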