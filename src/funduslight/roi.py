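"""Region-of-interest detection and pre-filtering.

A fundus photograph shows a bright, roughly circular eye region (the ROI)
surrounded by near-black padding.  All arithmetic downstream is restricted to
the ROI: the surround is zeroed and excluded from every filter, histogram and
statistic.  This module locates the ROI by thresholding the channel-mean
image, stores the per-pixel R/G and B/G ratios needed to restore color at the
end of the pipeline, and applies the ROI-masked 3 x 3 average pre-filter that
smooths pixel values along the ROI border.

Image conventions follow scikit-image: arrays are row-major with origin at
the top-left, a color image is an ``(H, W, 3)`` array, a channel is ``(H, W)``
float, and an ROI mask is ``(H, W)`` bool.  ``x`` denotes the column index,
so the "vertical center line" sits at column ``W / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, ROINotFoundError

__all__ = ["RatioMaps", "detect_roi", "compute_ratio_maps", "masked_average_3x3"]

# 4-connectivity structure for component labelling
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class RatioMaps:
    """Per-pixel R/G and B/G ratios, stored before any filtering.

    Finite and strictly positive on every ROI pixel (a zero green value is
    replaced by ``epsilon`` in the denominator); off-ROI entries are 1.
    """

    r_over_g: np.ndarray
    b_over_g: np.ndarray
    epsilon: float = 1.0


def _as_color(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError(f"expected an (H, W, 3) color image, got shape {img.shape}")
    return img.astype(float)


def detect_roi(
    image: np.ndarray,
    threshold: float = 20.0,
    *,
    largest_component: bool = True,
    fill_holes: bool = True,
    symmetrize: bool = True,
) -> np.ndarray:
    """Locate the eye region by thresholding the channel-mean image.

    Pixels whose mean intensity over the three channels exceeds ``threshold``
    are kept, reduced to the largest 4-connected component, interior holes
    are filled, and the mask is made symmetric about the vertical center
    line by union with its left-right mirror.  The mirror union (rather than
    intersection) ensures an ROI clipped on one side by a reflection artifact
    is completed, not shrunk.

    Parameters
    ----------
    image:
        ``(H, W, 3)`` color image on the 0-255 scale.
    threshold:
        Intensity cut on the channel mean; fundus surrounds are near black,
        so a low fixed value is robust.

    Returns
    -------
    ``(H, W)`` boolean mask.

    Raises
    ------
    ROINotFoundError
        If no pixel exceeds the threshold.
    """
    img = _as_color(image)
    mask = img.mean(axis=2) > threshold
    if not mask.any():
        raise ROINotFoundError(f"no pixel above threshold {threshold}; cannot locate the eye region")
    if largest_component:
        labels, n = ndimage.label(mask, structure=_CROSS)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = labels == sizes.argmax()
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if symmetrize:
        mask = mask | mask[:, ::-1]
    return mask


def compute_ratio_maps(image: np.ndarray, mask: np.ndarray, epsilon: float = 1.0) -> RatioMaps:
    """Store the R/G and B/G ratio of every ROI pixel for later color correction.

    A green value below ``epsilon`` is replaced by ``epsilon`` in the
    denominator so the ratios stay finite and bounded by 255; typical fundus
    pixels (G >> 1) are unaffected.  Ratios must be taken from the original,
    unfiltered channels.
    """
    img = _as_color(image)
    if img.shape[:2] != mask.shape:
        raise InvalidParameterError("image and mask shapes differ")
    g_safe = np.maximum(img[:, :, 1], epsilon)
    r_over_g = np.where(mask, img[:, :, 0] / g_safe, 1.0)
    b_over_g = np.where(mask, img[:, :, 2] / g_safe, 1.0)
    return RatioMaps(r_over_g=r_over_g, b_over_g=b_over_g, epsilon=float(epsilon))


def masked_average_3x3(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """ROI-masked 3 x 3 average filter.

    Each ROI pixel becomes the mean of the ROI-member pixels in its 3 x 3
    neighborhood; neighbors outside the ROI (or the image) are excluded from
    both the sum and the count, so border values are not dragged toward the
    zeroed surround.  Off-ROI pixels stay 0.
    """
    chan = np.asarray(channel, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if chan.shape != m.shape:
        raise InvalidParameterError("channel and mask shapes differ")
    ones = np.ones((3, 3))
    num = ndimage.convolve(np.where(m, chan, 0.0), ones, mode="constant", cval=0.0)
    den = ndimage.convolve(m.astype(float), ones, mode="constant", cval=0.0)
    out = np.zeros_like(chan)
    np.divide(num, den, out=out, where=m & (den > 0))
    return out
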