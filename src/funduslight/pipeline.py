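"""End-to-end enhancement pipeline and the multi-filter benchmark loop.

Stage order:

1.  split the image into R, G, B channels;
2.  store the R/G and B/G ratio maps from the original channels;
3.  locate and symmetrize the ROI by thresholding;
4.  smooth each channel with the ROI-masked 3 x 3 average pre-filter;
5.  estimate the background-brightness surface of each channel
    (flattened binomial by default; Gaussian or window-median baselines);
6.  shift each pixel's background to the 128 baseline and pool the three
    channel gaps into the full-information green channel;
7.  equalize the pooled channel with the constrained ROI-wide histogram
    equalization;
8.  rebuild the color image from the equalized green and the stored ratios.

The quality report carries the mean CIELAB lightness and the global
contrast factor of the input and output, plus their relative gains.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import adjust, background, color, equalize, io, metrics, roi
from .errors import InvalidParameterError
from .kernels import Kernel, gaussian_kernel, production_kernel

__all__ = ["PipelineConfig", "enhance", "benchmark", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "split-channels",
    "ratio-maps",
    "roi-detection",
    "pre-filter-3x3",
    "background-estimation",
    "luminosity-adjustment",
    "constrained-equalization",
    "color-recombination",
)

FILTER_FAMILIES = ("binomial", "gaussian", "median")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one enhancement run."""

    filter_family: str = "binomial"
    size: int = 41  # kernel / window side, odd
    alpha: float = 0.1  # binomial flattening factor
    sigma: float = 5.0  # gaussian spread
    threshold: float = 20.0  # ROI cut on the channel mean
    baseline: float = 128.0  # target background level
    clip_factor: float = 2.0  # equalization clip limit factor
    epsilon: float = 1.0  # zero-green guard for ratio maps
    dump_dir: Path | None = None  # write intermediate surfaces here

    def __post_init__(self) -> None:
        if self.filter_family not in FILTER_FAMILIES:
            raise InvalidParameterError(
                f"filter_family must be one of {FILTER_FAMILIES}, got {self.filter_family!r}"
            )
        if self.size < 1 or self.size % 2 == 0:
            raise InvalidParameterError(f"size must be an odd positive integer, got {self.size}")

    def build_kernel(self) -> Kernel | None:
        if self.filter_family == "binomial":
            return production_kernel(size=self.size, alpha=self.alpha)
        if self.filter_family == "gaussian":
            return gaussian_kernel(size=self.size, sigma=self.sigma)
        return None  # median: no kernel weights


def _surface(channel: np.ndarray, mask: np.ndarray, config: PipelineConfig) -> np.ndarray:
    kernel = config.build_kernel()
    if kernel is None:
        return background.masked_median_surface(channel, mask, window=config.size)
    return background.estimate_background(channel, mask, kernel)


def enhance(
    image: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, metrics.QualityReport]:
    """Run the full enhancement pipeline on an (H, W, 3) 8-bit image.

    Returns the enhanced image and a quality report with before/after
    luminosity, contrast and gains.
    """
    config = config or PipelineConfig()
    img = np.asarray(image, dtype=float)
    t0 = time.perf_counter()

    ratios = roi.compute_ratio_maps(img, np.ones(img.shape[:2], dtype=bool), config.epsilon)
    mask = roi.detect_roi(img, config.threshold)
    # ratios are only meaningful (and used) on ROI pixels
    logger.info("roi-detection: %d ROI pixels", int(mask.sum()))

    filtered = [roi.masked_average_3x3(img[:, :, c], mask) for c in range(3)]
    logger.info("pre-filter-3x3 done (%.2fs)", time.perf_counter() - t0)

    surfaces = tuple(_surface(ch, mask, config) for ch in filtered)
    logger.info("background-estimation done (%.2fs)", time.perf_counter() - t0)

    stacked = np.stack(filtered, axis=2)
    adjusted = adjust.adjust_all(stacked, surfaces, mask, config.baseline)
    eg = equalize.equalize_roi(adjusted.agf, mask, config.clip_factor)
    enhanced = color.recombine(eg, ratios, mask)
    logger.info("pipeline done (%.2fs)", time.perf_counter() - t0)

    if config.dump_dir is not None:
        dump = Path(config.dump_dir)
        dump.mkdir(parents=True, exist_ok=True)
        for name, surf in zip("rgb", surfaces):
            io.save_surface_16bit(dump / f"background_{name}.png", surf)
        for name, chan in (("agf", adjusted.agf), ("eg", eg)):
            io.save_surface_16bit(dump / f"adjusted_{name}.png", chan)

    kernel = config.build_kernel()
    descriptor = kernel.descriptor() if kernel else {"family": "median", "size": config.size}
    report = metrics.gains(
        before=(metrics.mean_luminosity(image, mask), metrics.global_contrast_factor(image, mask)),
        after=(
            metrics.mean_luminosity(enhanced, mask),
            metrics.global_contrast_factor(enhanced, mask),
        ),
        filter_descriptor=descriptor,
    )
    return enhanced, report


def benchmark(
    images: list[np.ndarray],
    config: PipelineConfig | None = None,
    filters: tuple[str, ...] = FILTER_FAMILIES,
) -> dict[str, list[metrics.QualityReport]]:
    """Run every filter family over every image; append an average row per family.

    Per-image failures are logged and recorded as None so one bad input does
    not abort the sweep.
    """
    if not images or not filters:
        raise InvalidParameterError("benchmark needs at least one image and one filter")
    config = config or PipelineConfig()
    table: dict[str, list] = {}
    for family in filters:
        cfg = PipelineConfig(
            filter_family=family,
            size=config.size,
            alpha=config.alpha,
            sigma=config.sigma,
            threshold=config.threshold,
            baseline=config.baseline,
            clip_factor=config.clip_factor,
            epsilon=config.epsilon,
        )
        rows = []
        for i, img in enumerate(images):
            try:
                _, report = enhance(img, cfg)
                rows.append(report)
            except Exception:
                logger.exception("benchmark: image %d failed with filter %s", i, family)
                rows.append(None)
        completed = [r for r in rows if r is not None]
        if completed:
            rows.append(metrics.average_report(completed))
        table[family] = rows
    return table
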