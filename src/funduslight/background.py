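"""Background-brightness surface estimation.

The luminosity of a fundus photograph varies smoothly across the eye region
(vignetting, uneven illumination, boundary reflection) while foreground
structures — vessels, the optic disc, hemorrhages, exudates — sit on top of
that slowly varying background as local deviations.  Convolving a channel
with a large flat-ish kernel averages the foreground away and leaves the
background brightness surface BB(x, y).

Near the ROI border part of the kernel footprint falls outside the eye
region.  Those samples are simply dropped and the remaining kernel weights
renormalized per pixel, i.e. for every ROI pixel

    BB(x, y) = sum_{(m, n) in N} b(m, n) * i(x - m, y - n) / D,
    D = sum_{(m, n) in N} b(m, n),

where N runs over footprint positions that are inside both the ROI and the
image.  This normalized masked convolution reproduces constants exactly
everywhere, including at the border, which is what makes the subsequent
shift-to-baseline adjustment well behaved there.

Pixels outside the image bounds are treated exactly like off-ROI pixels.
The per-pixel renormalization breaks separability, so the convolution is
evaluated with the full 2-D kernel over the masked support (a numerator and
a denominator convolution).  The estimate is finished with a 3 x 3
ROI-masked average smoothing pass.

A window median (computed via a 256-bin histogram) and a floored Gaussian
serve as baseline background estimators in the same framework.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .kernels import Kernel
from .roi import masked_average_3x3

__all__ = [
    "masked_normalized_convolve",
    "estimate_background",
    "masked_median_surface",
]


def masked_normalized_convolve(channel: np.ndarray, mask: np.ndarray, kernel: Kernel) -> np.ndarray:
    """ROI-masked convolution with per-pixel weight renormalization.

    Off-ROI and out-of-bounds footprint samples are dropped and the surviving
    kernel coefficients renormalized to unit sum, so the result at each ROI
    pixel is a weighted mean of ROI member values only.  Off-ROI output is 0.
    """
    chan = np.asarray(channel, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if chan.shape != m.shape:
        raise InvalidParameterError("channel and mask shapes differ")
    if not m.any():
        raise InvalidParameterError("mask is empty")
    k = kernel.coefficients
    if np.any(k <= 0):
        raise InvalidParameterError("kernel coefficients must be strictly positive")
    if k.shape[0] > 2 * min(chan.shape) + 1:
        raise InvalidParameterError(
            f"kernel size {k.shape[0]} too large for image of shape {chan.shape}"
        )
    num = ndimage.convolve(np.where(m, chan, 0.0), k, mode="constant", cval=0.0)
    den = ndimage.convolve(m.astype(float), k, mode="constant", cval=0.0)
    out = np.zeros_like(chan)
    # the center pixel is an ROI member, so den > 0 wherever m is true
    np.divide(num, den, out=out, where=m)
    return out


def estimate_background(channel: np.ndarray, mask: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Background-brightness surface: masked convolution plus 3 x 3 smoothing.

    Every ROI value of the result is a convex combination of ROI input
    values, so the surface never leaves the input's ROI min-max range, and a
    channel constant over the ROI is reproduced exactly.
    """
    return masked_average_3x3(masked_normalized_convolve(channel, mask, kernel), mask)


def _box_count(member: np.ndarray, window: int) -> np.ndarray:
    """Number of true entries of ``member`` in each window x window box (exact integers)."""
    w = window // 2
    padded = np.zeros((member.shape[0] + 2 * w + 1, member.shape[1] + 2 * w + 1), dtype=np.int64)
    padded[w + 1 : w + 1 + member.shape[0], w + 1 : w + 1 + member.shape[1]] = member
    ii = padded.cumsum(axis=0).cumsum(axis=1)  # integral image
    h, wid = member.shape
    r0, r1 = np.arange(h), np.arange(h) + 2 * w + 1
    c0, c1 = np.arange(wid), np.arange(wid) + 2 * w + 1
    return ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]


def masked_median_surface(
    channel: np.ndarray, mask: np.ndarray, window: int = 41, smooth: bool = True
) -> np.ndarray:
    """Background surface from a sliding-window median over ROI members.

    The median in each ``window x window`` neighborhood is found by sweeping
    a 256-bin histogram of the 8-bit values: cumulative member counts per
    grey level are accumulated with integral images, and the median of a
    neighborhood with ``n`` members is the smallest level whose cumulative
    count reaches ``ceil(n / 2)`` — the lower median when ``n`` is even.
    A 3 x 3 ROI-masked average smoothing finishes the surface, matching the
    framework shared by all background estimators; pass ``smooth=False`` for
    the raw median.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError(f"window must be an odd positive integer, got {window!r}")
    chan = np.asarray(channel, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if chan.shape != m.shape:
        raise InvalidParameterError("channel and mask shapes differ")
    levels = np.clip(np.rint(chan), 0, 255).astype(np.int16)

    members = _box_count(m, window)
    rank = (members + 1) // 2  # lower-median rank, 1-based
    median = np.zeros(chan.shape, dtype=np.int16)
    unresolved = m.copy()
    cum = np.zeros(chan.shape, dtype=np.int64)
    for g in range(256):
        if not unresolved.any():
            break
        cum += _box_count(m & (levels == g), window)
        hit = unresolved & (cum >= rank)
        median[hit] = g
        unresolved &= ~hit
    surface = np.where(m, median.astype(float), 0.0)
    return masked_average_3x3(surface, m) if smooth else surface
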