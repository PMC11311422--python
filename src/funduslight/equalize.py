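"""Constrained, ROI-wide adaptive histogram equalization.

After luminosity adjustment the ROI histogram is concentrated around the
mid-grey baseline and the channel looks washed out.  A contrast-limited
equalization stretches it, but with two constraints that protect detail:

* the number of distinct grey levels is preserved — distinct inputs map to
  distinct outputs, so no two structures merge;
* the gap between consecutive occupied grey levels may grow but never
  shrink, so intensity order and local separability are kept.

The clip limit is expressed relative to the uniform distribution over the
*occupied* bins — ``clip_factor * pixel_count / occupied_bins`` — because
the adjusted histogram occupies few bins near the baseline and a limit
relative to all 256 bins would almost never bind.  Clipped excess is
redistributed uniformly over the occupied bins in a single pass.  The whole
ROI is equalized as one tile: no spatial tiling or bilinear blending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, MappingError

__all__ = ["LevelMapping", "build_constrained_mapping", "apply_mapping"]


@dataclass(frozen=True)
class LevelMapping:
    """Monotone mapping of the occupied grey levels of an ROI.

    Both lists are strictly increasing, equal length, and for every
    consecutive pair the output gap is at least the input gap.
    """

    input_levels: np.ndarray  # sorted distinct integer levels present in the ROI
    output_levels: np.ndarray  # mapped levels, reals in [0, 255]

    def as_lut(self) -> np.ndarray:
        """256-entry lookup table; unoccupied levels hold NaN."""
        lut = np.full(256, np.nan)
        lut[self.input_levels] = self.output_levels
        return lut


def _roi_levels(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    chan = np.asarray(channel, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if chan.shape != m.shape:
        raise InvalidParameterError("channel and mask shapes differ")
    if not m.any():
        raise InvalidParameterError("mask is empty")
    return np.clip(np.rint(chan[m]), 0, 255).astype(np.int64)


def build_constrained_mapping(
    channel: np.ndarray, mask: np.ndarray, clip_factor: float = 2.0
) -> LevelMapping:
    """Derive the constrained equalization mapping from the ROI histogram.

    Steps: build the 256-bin ROI histogram; clip each occupied bin at
    ``clip_factor`` times the per-occupied-bin uniform count, redistributing
    the excess uniformly (one pass); map the clipped cumulative distribution
    onto [0, 255]; then sweep left to right raising each output so that no
    consecutive-level gap falls below its input gap.  If the sweep pushes the
    top level past 255, the increments are shrunk by the largest common
    factor that still respects every input gap (shifting the anchor down as
    a last resort — always feasible since the input span is at most 255).
    """
    vals = _roi_levels(channel, mask)
    hist = np.bincount(vals, minlength=256)
    levels = np.flatnonzero(hist)
    n_occ = levels.size
    if n_occ == 1:
        # degenerate histogram: no spread possible without creating levels
        lv = levels.astype(float)
        return LevelMapping(input_levels=levels, output_levels=lv)

    counts = hist[levels].astype(float)
    limit = clip_factor * vals.size / n_occ
    excess = np.maximum(counts - limit, 0.0).sum()
    counts = np.minimum(counts, limit) + excess / n_occ

    cdf = np.cumsum(counts) / counts.sum()
    target = np.floor(cdf * 255.0)

    gaps = np.diff(levels).astype(float)
    out = np.empty(n_occ)
    out[0] = target[0]
    for k in range(1, n_occ):
        out[k] = max(target[k], out[k - 1] + gaps[k - 1])

    if out[-1] > 255.0:
        # shrink the expansion (the part of each increment above its input
        # gap) by the largest common factor s in [0, 1] that fits in [0, 255];
        # drop the anchor as a last resort (always feasible: input span <= 255)
        d = np.diff(out)
        extra = d - gaps  # >= 0 by construction of the gap pass
        anchor = min(out[0], 255.0 - gaps.sum())
        slack = 255.0 - anchor - gaps.sum()
        s = min(1.0, slack / extra.sum()) if extra.sum() > 0 else 0.0
        out = anchor + np.concatenate(([0.0], np.cumsum(gaps + s * extra)))

    return LevelMapping(input_levels=levels, output_levels=out)


def apply_mapping(channel: np.ndarray, mask: np.ndarray, mapping: LevelMapping) -> np.ndarray:
    """Replace each ROI pixel's grey level by its mapped level; off-ROI stays 0."""
    chan = np.asarray(channel, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if chan.shape != m.shape:
        raise InvalidParameterError("channel and mask shapes differ")
    levels = np.clip(np.rint(chan), 0, 255).astype(np.int64)
    lut = mapping.as_lut()
    mapped = lut[levels]
    if np.isnan(mapped[m]).any():
        missing = np.unique(levels[m & np.isnan(mapped)])
        raise MappingError(f"ROI grey levels {missing.tolist()} missing from the level mapping")
    return np.where(m, mapped, 0.0)


def equalize_roi(channel: np.ndarray, mask: np.ndarray, clip_factor: float = 2.0) -> np.ndarray:
    """Convenience: build the constrained mapping and apply it."""
    return apply_mapping(channel, mask, build_constrained_mapping(channel, mask, clip_factor))
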