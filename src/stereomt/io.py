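"""File I/O for stereo artifacts: PFM disparity, 8/16-bit PNG, JSON sidecars.

PFM files are written little-endian ("Pf", scale -1.0) with rows stored
bottom-up, the standard layout for disparity interchange; 16-bit PNG stores
disparity at a x256 fixed-point scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "write_pfm", "read_pfm", "write_disparity_png16", "read_disparity_png16",
    "write_image_png", "write_mask_png", "read_mask_png", "write_sidecar",
]

PNG16_SCALE = 256.0


def write_pfm(path, data: np.ndarray) -> None:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("PFM writer expects a 2-D map")
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{data.shape[1]} {data.shape[0]}\n".encode())
        fh.write(b"-1.0\n")  # negative scale marks little-endian
        fh.write(np.flipud(data).astype("<f4").tobytes())


def read_pfm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header != b"Pf":
            raise ValueError(f"not a grayscale PFM file: header {header!r}")
        width, height = map(int, fh.readline().split())
        scale = float(fh.readline())
        dtype = "<f4" if scale < 0 else ">f4"
        data = np.frombuffer(fh.read(width * height * 4), dtype=dtype)
    return np.flipud(data.reshape(height, width)).astype(np.float32)


def write_disparity_png16(path, disparity: np.ndarray) -> None:
    scaled = np.clip(np.asarray(disparity, dtype=np.float64) * PNG16_SCALE, 0, 65535)
    iio.imwrite(path, np.rint(scaled).astype(np.uint16))


def read_disparity_png16(path) -> np.ndarray:
    return iio.imread(path).astype(np.float32) / PNG16_SCALE


def write_image_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64) * 255.0, 0, 255)
    iio.imwrite(path, arr.astype(np.uint8))


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_mask_png(path) -> np.ndarray:
    return iio.imread(path) > 127


def write_sidecar(path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True) + "\n")
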