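"""Color restoration from the equalized green channel and stored ratios.

Directly recombining independently equalized channels distorts the color
tone, so the enhanced image is rebuilt around the equalized green channel
EG as the anchor: the new red and blue are the original per-pixel R/G and
B/G ratios times EG, and the new green is EG itself.  Scaling all channels
by the same per-pixel factor preserves hue while adopting the equalized
luminosity.

Products are rounded to the nearest integer (half away from zero) and
clamped to the 8-bit range; extreme ratios saturate rather than rescale,
accepting a minor hue shift at specular pixels.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .roi import RatioMaps

__all__ = ["recombine"]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def recombine(eg: np.ndarray, ratios: RatioMaps, mask: np.ndarray) -> np.ndarray:
    """Rebuild the 8-bit color image from the equalized green and ratio maps.

    On ROI pixels: ``R = clamp(round(r_over_g * EG))``, ``G = clamp(round(EG))``,
    ``B = clamp(round(b_over_g * EG))``; off-ROI pixels are black.
    """
    eg_arr = np.asarray(eg, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if eg_arr.shape != m.shape or ratios.r_over_g.shape != m.shape:
        raise InvalidParameterError("eg, ratio maps and mask shapes differ")
    out = np.zeros(eg_arr.shape + (3,), dtype=np.uint8)
    for c, plane in enumerate((ratios.r_over_g * eg_arr, eg_arr, ratios.b_over_g * eg_arr)):
        out[:, :, c] = np.where(m, np.clip(_round_half_away(plane), 0, 255), 0).astype(np.uint8)
    return out
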