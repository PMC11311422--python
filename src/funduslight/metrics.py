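"""Image-quality metrics: mean CIELAB lightness and a multi-resolution
global contrast factor (GCF), with relative gain reports.

Luminosity is the mean L* component (sRGB -> CIE L*a*b*, D65 white,
L in [0, 100]) over the ROI.

Contrast is a three-resolution global contrast factor: the image lightness
(L* rescaled to [0, 1]) is repeatedly downsampled by 2 x 2 superpixel
averaging; at each resolution the local contrast of a pixel is the mean
absolute lightness difference against its in-ROI 8-neighbors, the level
contrast is the mean local contrast over in-ROI pixels, and the GCF is the
weighted sum of the level contrasts with weights 0.12, 0.142 and 0.154
(finest to coarsest).  The ROI mask is carried through the pyramid as a
mask fraction; a superpixel counts as in-ROI when its fraction exceeds 1/2.

Gains are plain relative changes: ``(after - before) / before * 100`` in
percent, for both luminosity and contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
from skimage.color import rgb2lab

from .errors import InvalidParameterError, UndefinedGainError

__all__ = [
    "GCFConfig",
    "QualityReport",
    "mean_luminosity",
    "global_contrast_factor",
    "gains",
    "average_report",
]

logger = logging.getLogger(__name__)

_NEIGHBOR_OFFSETS = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


@dataclass(frozen=True)
class GCFConfig:
    """Resolution count and per-resolution weights of the contrast factor."""

    weights: tuple[float, ...] = (0.12, 0.142, 0.154)
    resolutions: int = 3

    def __post_init__(self) -> None:
        if len(self.weights) != self.resolutions:
            raise InvalidParameterError("number of weights must equal number of resolutions")
        if any(w <= 0 for w in self.weights):
            raise InvalidParameterError("weights must be positive")


@dataclass
class QualityReport:
    """Before/after luminosity and contrast of one enhancement run."""

    luminosity_before: float
    contrast_before: float
    luminosity_after: float = float("nan")
    contrast_after: float = float("nan")
    luminosity_gain_pct: float = float("nan")
    contrast_gain_pct: float = float("nan")
    filter_descriptor: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _lightness(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidParameterError(f"expected (H, W, 3) color image, got {img.shape}")
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return rgb2lab(img)[:, :, 0]


def mean_luminosity(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean CIELAB L* over the ROI (0 = black, 100 = white)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise InvalidParameterError("mask is empty")
    return float(_lightness(image)[m].mean())


def _downsample2(arr: np.ndarray) -> np.ndarray:
    """2 x 2 block mean, zero-padding odd edges."""
    h, w = arr.shape
    h2, w2 = (h + 1) // 2, (w + 1) // 2
    padded = np.zeros((h2 * 2, w2 * 2), dtype=float)
    padded[:h, :w] = arr
    return 0.25 * (padded[0::2, 0::2] + padded[0::2, 1::2] + padded[1::2, 0::2] + padded[1::2, 1::2])


def _level_contrast(lightness: np.ndarray, mask: np.ndarray) -> float:
    """Mean over in-ROI pixels of the mean |dL| against in-ROI 8-neighbors."""
    h, w = lightness.shape
    diff_sum = np.zeros((h, w))
    count = np.zeros((h, w))
    for dy, dx in _NEIGHBOR_OFFSETS:
        src = (slice(max(0, -dy), min(h, h - dy)), slice(max(0, -dx), min(w, w - dx)))
        dst = (slice(max(0, dy), min(h, h + dy)), slice(max(0, dx), min(w, w + dx)))
        pair = mask[dst] & mask[src]
        diff_sum[dst] += np.where(pair, np.abs(lightness[dst] - lightness[src]), 0.0)
        count[dst] += pair
    local = np.zeros((h, w))
    np.divide(diff_sum, count, out=local, where=count > 0)
    return float(local[mask].mean())


def global_contrast_factor(
    image: np.ndarray, mask: np.ndarray, config: GCFConfig | None = None
) -> float:
    """Weighted multi-resolution mean-absolute-neighbor-difference contrast."""
    config = config or GCFConfig()
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise InvalidParameterError("mask is empty")
    lightness = _lightness(image) / 100.0
    frac = m.astype(float)
    gcf = 0.0
    for weight in config.weights:
        level_mask = frac > 0.5
        if not level_mask.any():
            logger.warning("ROI vanished at a coarser contrast resolution; level contributes 0")
        else:
            gcf += weight * _level_contrast(lightness, level_mask)
        lightness = _downsample2(lightness)
        frac = _downsample2(frac)
    return gcf


def gains(
    before: tuple[float, float],
    after: tuple[float, float],
    filter_descriptor: dict | None = None,
) -> QualityReport:
    """Relative luminosity and contrast gains, in percent.

    ``before`` and ``after`` are (luminosity, contrast) pairs.
    """
    lb, cb = before
    la, ca = after
    if lb <= 0 or cb <= 0:
        raise UndefinedGainError(f"gain undefined for non-positive baseline (L={lb}, C={cb})")
    return QualityReport(
        luminosity_before=lb,
        contrast_before=cb,
        luminosity_after=la,
        contrast_after=ca,
        luminosity_gain_pct=(la - lb) / lb * 100.0,
        contrast_gain_pct=(ca - cb) / cb * 100.0,
        filter_descriptor=filter_descriptor or {},
    )


def average_report(reports: list[QualityReport]) -> QualityReport:
    """Column-wise average of several reports, with gains recomputed.

    The gains are recomputed from the averaged before/after values (not
    averaged themselves), so the summary row satisfies the same gain
    formulas as the per-image rows.
    """
    if not reports:
        raise InvalidParameterError("cannot average an empty list of reports")
    lb = float(np.mean([r.luminosity_before for r in reports]))
    cb = float(np.mean([r.contrast_before for r in reports]))
    la = float(np.mean([r.luminosity_after for r in reports]))
    ca = float(np.mean([r.contrast_after for r in reports]))
    return gains((lb, cb), (la, ca), filter_descriptor={"aggregate": len(reports)})
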