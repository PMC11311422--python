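"""Luminosity adjustment: shift every pixel's background to a common baseline.

With the background-brightness surface in hand, each channel value is the
background plus a per-pixel "gap" (positive for bright structures such as
exudates, negative for dark ones such as vessels).  Adjustment replaces the
uneven background with the fixed mid-grey baseline 128 while carrying the
gap over unchanged:

    A_c(x, y) = 128 + c(x, y) - BB_c(x, y)        for c in {R, G, B}

so the adjusted ROI has uniform background luminosity and preserved local
structure.  Additionally a "full-information" green channel pools the gaps
of all three channels,

    AGF(x, y) = 128 + R + G + B - BBR - BBG - BBB,

exploiting that the red and blue gaps co-vary with the green one: their sum
raises the contrast and stability of the green channel, which later anchors
the color reconstruction.

The model is strictly additive (no multiplicative/retinex correction).
Adjusted values are clamped to [0, 255] so the histogram-equalization stage
receives an 8-bit range; clamping is the only place the gap is not preserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["AdjustedChannels", "adjust_channel", "adjust_green_full", "adjust_all"]

BASELINE = 128.0


@dataclass(frozen=True)
class AdjustedChannels:
    """Adjusted red, green, blue and full-information green surfaces."""

    ar: np.ndarray
    ag: np.ndarray
    ab: np.ndarray
    agf: np.ndarray
    baseline: float = BASELINE


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise InvalidParameterError(f"shape mismatch: {sorted(shapes)}")


def adjust_channel(
    channel: np.ndarray,
    surface: np.ndarray,
    mask: np.ndarray,
    baseline: float = BASELINE,
) -> np.ndarray:
    """``clamp(baseline + channel - surface, 0, 255)`` on the ROI, 0 outside."""
    chan = np.asarray(channel, dtype=float)
    surf = np.asarray(surface, dtype=float)
    m = np.asarray(mask, dtype=bool)
    _check_shapes(chan, surf, m)
    return np.where(m, np.clip(baseline + chan - surf, 0.0, 255.0), 0.0)


def adjust_green_full(
    image: np.ndarray,
    surfaces: tuple[np.ndarray, np.ndarray, np.ndarray],
    mask: np.ndarray,
    baseline: float = BASELINE,
) -> np.ndarray:
    """Full-information adjusted green: baseline plus the sum of all three gaps.

    ``surfaces`` are the (red, green, blue) background-brightness surfaces.
    When the red and blue gaps are identically zero this reduces to
    :func:`adjust_channel` on the green channel.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError(f"expected (H, W, 3) image, got {img.shape}")
    gap_sum = np.zeros(img.shape[:2])
    for c in range(3):
        surf = np.asarray(surfaces[c], dtype=float)
        _check_shapes(img[:, :, c], surf, m)
        gap_sum += img[:, :, c] - surf
    return np.where(m, np.clip(baseline + gap_sum, 0.0, 255.0), 0.0)


def adjust_all(
    image: np.ndarray,
    surfaces: tuple[np.ndarray, np.ndarray, np.ndarray],
    mask: np.ndarray,
    baseline: float = BASELINE,
) -> AdjustedChannels:
    """Adjust all three channels and build the full-information green."""
    ar, ag, ab = (
        adjust_channel(np.asarray(image, dtype=float)[:, :, c], surfaces[c], mask, baseline)
        for c in range(3)
    )
    agf = adjust_green_full(image, surfaces, mask, baseline)
    return AdjustedChannels(ar=ar, ag=ag, ab=ab, agf=agf, baseline=float(baseline))
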