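"""Raster input/output: 8-bit RGB images and 16-bit intermediate dumps."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ImageFormatError

__all__ = ["load_rgb", "save_image", "save_surface_16bit", "load_surface_16bit"]


def load_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as an (H, W, 3) uint8 array.

    Alpha channels are dropped.  Greyscale inputs are rejected: the pipeline
    needs all three color channels to store the R/G and B/G ratios.
    """
    path = Path(path)
    try:
        img = np.asarray(iio.imread(path))
    except Exception as exc:  # imageio plugins raise a mix of exception types
        raise ImageFormatError(f"cannot decode image file {path}: {exc}") from exc
    if img.ndim == 2 or (img.ndim == 3 and img.shape[2] == 1):
        raise ImageFormatError(
            f"{path} is greyscale; a 3-channel RGB fundus image is required"
        )
    if img.ndim != 3 or img.shape[2] < 3:
        raise ImageFormatError(f"{path} has unsupported shape {img.shape}")
    img = img[:, :, :3]
    if img.dtype == np.uint16:
        img = (img // 257).astype(np.uint8)
    elif img.dtype != np.uint8:
        img = np.clip(np.rint(img.astype(float)), 0, 255).astype(np.uint8)
    return img


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit color image as PNG or TIFF (by extension)."""
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def save_surface_16bit(path: str | Path, surface: np.ndarray, scale: float = 256.0) -> None:
    """Dump a real-valued surface (range [0, 255]) as a 16-bit greyscale PNG.

    Values are stored as ``round(value * scale)`` so the round trip through
    :func:`load_surface_16bit` loses less than ``1 / (2 * scale)`` levels.
    """
    coded = np.clip(np.rint(np.asarray(surface, dtype=float) * scale), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), coded)


def load_surface_16bit(path: str | Path, scale: float = 256.0) -> np.ndarray:
    """Read back a surface written by :func:`save_surface_16bit`."""
    return np.asarray(iio.imread(Path(path)), dtype=float) / scale
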