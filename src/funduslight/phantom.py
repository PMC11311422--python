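"""Seeded synthetic fundus phantoms with known ground truth.

Real fundus photographs cannot ship with a test suite, so every stage of the
pipeline is exercised on deterministic phantoms that reproduce the features
the method targets: a bright disc-shaped eye region on a black surround,
smooth non-uniform illumination (a linear gradient plus an optional bright
reflection bump centered on the ROI border), dark curvilinear vessels,
small bright exudate spots, background channel means ordered R >= G >= B,
and a little sensor noise.  The generator returns the clean background
surfaces and the foreground mask alongside the image, so estimation error
and equalization accuracy can be measured against truth.

The phantoms are deliberately schematic: vessels are constant-darkness
random-walk strokes rather than branching trees, the optic disc is absent,
and illumination is low-order smooth.  They validate the arithmetic of the
pipeline, not its photorealism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = [
    "ReflectionSpec",
    "IlluminationSpec",
    "VesselSpec",
    "ExudateSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
]


@dataclass(frozen=True)
class ReflectionSpec:
    """Bright over-exposure blob centered on the ROI border."""

    amplitude: float = 60.0  # intensity levels added at the bump center
    angle_deg: float = 90.0  # border position, counterclockwise from +x
    scale: float = 80.0  # Gaussian spatial scale, pixels


@dataclass(frozen=True)
class IlluminationSpec:
    """Smooth per-channel background illumination model.

    ``base`` is the (R, G, B) background level at the image center and must
    be ordered R >= G >= B — the fundus color model.  ``gradient`` is the
    total linear variation in levels across the full (height, width).
    """

    base: tuple[float, float, float] = (120.0, 75.0, 38.0)
    gradient: tuple[float, float] = (0.0, 40.0)
    reflection: ReflectionSpec | None = field(default_factory=ReflectionSpec)


@dataclass(frozen=True)
class VesselSpec:
    count: int = 8
    width: float = 3.0  # stroke width, pixels
    darkness: float = 40.0  # levels subtracted along the stroke


@dataclass(frozen=True)
class ExudateSpec:
    count: int = 6
    radius: float = 5.0  # pixels
    brightness: float = 50.0  # levels added inside the disc


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 500
    width: int = 700
    roi_radius_fraction: float = 0.94  # of min(height, width) / 2
    illumination: IlluminationSpec = field(default_factory=IlluminationSpec)
    vessels: VesselSpec = field(default_factory=VesselSpec)
    exudates: ExudateSpec = field(default_factory=ExudateSpec)
    noise_sigma: float = 1.0  # Gaussian, clipped with the image
    seed: int = 0


@dataclass(frozen=True)
class PhantomTruth:
    """A generated phantom with its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    roi: np.ndarray  # (H, W) bool
    true_background: tuple[np.ndarray, np.ndarray, np.ndarray]  # per-channel float
    foreground_mask: np.ndarray  # (H, W) bool
    spec: PhantomSpec


def _draw_vessels(rng: np.random.Generator, roi: np.ndarray, spec: VesselSpec) -> np.ndarray:
    """Dark-stroke mask from smooth random walks inside the ROI."""
    h, w = roi.shape
    strokes = np.zeros((h, w), dtype=bool)
    inside = np.argwhere(roi)
    n_steps = int(1.2 * min(h, w))
    for _ in range(spec.count):
        y, x = inside[rng.integers(len(inside))].astype(float)
        heading = rng.uniform(0.0, 2.0 * math.pi)
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.15)
            y += math.sin(heading)
            x += math.cos(heading)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w) or not roi[iy, ix]:
                break
            strokes[iy, ix] = True
    if strokes.any() and spec.width > 1:
        r = int(round(spec.width / 2))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        strokes = ndimage.binary_dilation(strokes, structure=yy**2 + xx**2 <= r**2)
    return strokes & roi


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render a phantom deterministically from its spec.

    The image is ``clip(true_background + foreground deltas + noise)``
    rounded to 8 bits inside the ROI and 0 outside; the same seed yields a
    bit-identical phantom on every run and platform.
    """
    h, w = spec.height, spec.width
    if h < 8 or w < 8:
        raise InvalidParameterError(f"phantom size {h}x{w} too small")
    base = spec.illumination.base
    if not (base[0] >= base[1] >= base[2]):
        raise InvalidParameterError(f"background base must be ordered R >= G >= B, got {base}")
    radius = spec.roi_radius_fraction * min(h, w) / 2.0
    if radius < 4:
        raise InvalidParameterError("ROI radius leaves no usable eye region")
    rng = np.random.default_rng(spec.seed)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    gy, gx = spec.illumination.gradient
    ramp = gy * (yy - cy) / h + gx * (xx - cx) / w
    bump = np.zeros((h, w))
    refl = spec.illumination.reflection
    if refl is not None and refl.amplitude != 0.0:
        theta = math.radians(refl.angle_deg)
        by, bx = cy - radius * math.sin(theta), cx + radius * math.cos(theta)
        bump = refl.amplitude * np.exp(
            -((yy - by) ** 2 + (xx - bx) ** 2) / (2.0 * refl.scale**2)
        )
    true_background = tuple(
        np.where(roi, np.clip(b + ramp + bump, 0.0, 255.0), 0.0) for b in base
    )

    delta = np.zeros((h, w))
    foreground = np.zeros((h, w), dtype=bool)
    if spec.vessels.count > 0:
        strokes = _draw_vessels(rng, roi, spec.vessels)
        delta -= spec.vessels.darkness * strokes
        foreground |= strokes
    if spec.exudates.count > 0:
        inner = radius - spec.exudates.radius - 2
        for _ in range(spec.exudates.count):
            rho = math.sqrt(rng.uniform(0.0, 1.0)) * max(inner, 1.0)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            ey, ex = cy + rho * math.sin(ang), cx + rho * math.cos(ang)
            disc = (yy - ey) ** 2 + (xx - ex) ** 2 <= spec.exudates.radius**2
            disc &= roi
            delta += spec.exudates.brightness * disc
            foreground |= disc
    noise = rng.normal(0.0, spec.noise_sigma, (h, w, 3)) if spec.noise_sigma > 0 else 0.0

    image = np.zeros((h, w, 3), dtype=np.uint8)
    for c in range(3):
        plane = true_background[c] + delta
        if spec.noise_sigma > 0:
            plane = plane + noise[:, :, c]
        image[:, :, c] = np.where(roi, np.clip(np.rint(plane), 0, 255), 0).astype(np.uint8)

    return PhantomTruth(
        image=image,
        roi=roi,
        true_background=true_background,
        foreground_mask=foreground,
        spec=spec,
    )
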