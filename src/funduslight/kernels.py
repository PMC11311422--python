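"""Smoothing-kernel construction.

Background brightness is estimated by convolving each color channel with a
large, nearly flat, symmetric low-pass kernel.  The production kernel is a
binomial filter — the coefficients of repeated convolution of ``[1, 1]`` with
itself, i.e. a row of Pascal's triangle — which approximates a Gaussian but is
built from exact integer arithmetic.  Because a raw binomial kernel is far too
peaky to level out foreground structures (vessels, exudates), its coefficients
are rescaled to a fixed maximum, flattened by a factor ``alpha`` and floored
at 1, which moves it continuously toward a box filter as ``alpha`` shrinks.

A floored Gaussian and the implied flat (box) kernel are provided as
baselines for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "Kernel",
    "binomial_1d",
    "binomial_2d",
    "scale_and_flatten",
    "gaussian_kernel",
]


@dataclass(frozen=True)
class Kernel:
    """A square, symmetric, strictly positive filter-coefficient matrix.

    Attributes
    ----------
    coefficients:
        ``(2*half_width+1, 2*half_width+1)`` array of positive reals with the
        maximum at the center.
    half_width:
        Number of pixels the footprint extends from the center in each
        direction.
    family:
        ``"binomial"``, ``"gaussian"`` or ``"average"``.
    alpha:
        Flattening factor (binomial family only).
    sigma:
        Spread in pixels (gaussian family only).
    """

    coefficients: np.ndarray
    half_width: int
    family: str
    alpha: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] % 2 == 0:
            raise InvalidParameterError(
                f"kernel must be square with odd size, got shape {c.shape}"
            )
        if c.shape[0] != 2 * self.half_width + 1:
            raise InvalidParameterError(
                f"size {c.shape[0]} inconsistent with half_width {self.half_width}"
            )
        object.__setattr__(self, "coefficients", c)

    @property
    def size(self) -> int:
        return self.coefficients.shape[0]

    def descriptor(self) -> dict:
        """JSON-serializable summary of the kernel's construction."""
        d = {"family": self.family, "size": self.size}
        if self.alpha is not None:
            d["alpha"] = self.alpha
        if self.sigma is not None:
            d["sigma"] = self.sigma
        return d


def _check_half_width(w) -> int:
    if not isinstance(w, (int, np.integer)) or isinstance(w, bool) or w < 0:
        raise InvalidParameterError(f"half-width must be a non-negative integer, got {w!r}")
    return int(w)


def binomial_1d(w: int) -> np.ndarray:
    """Normalized 1-D binomial coefficients of length ``2w + 1``.

    Cascaded convolution of ``[1, 1]`` with itself ``2w`` times yields row
    ``2w`` of Pascal's triangle, ``C(2w, k)``; dividing by the row sum
    ``4**w`` gives a unit-sum, palindromic, unimodal smoothing vector.
    Integer accumulation is exact up to ``w = 26`` (C(52, 26) < 2**53).
    """
    w = _check_half_width(w)
    row = [1]
    for _ in range(2 * w):
        row = [1] + [row[i] + row[i + 1] for i in range(len(row) - 1)] + [1]
    return np.array(row, dtype=float) / float(4**w)


def binomial_2d(w: int) -> Kernel:
    """2-D binomial kernel: the outer product of :func:`binomial_1d` with itself."""
    b = binomial_1d(w)
    return Kernel(coefficients=np.outer(b, b), half_width=w, family="binomial", alpha=1.0)


def scale_and_flatten(
    kernel: Kernel,
    alpha: float,
    max_target: float = 100.0,
    floor: float = 1.0,
) -> Kernel:
    """Rescale a kernel to a fixed peak, flatten by ``alpha`` and floor at 1.

    The coefficients are scaled so the maximum equals ``max_target``, then
    multiplied by ``alpha`` and lower-limited at ``floor`` elementwise.  At
    ``alpha * max_target <= floor`` every coefficient hits the floor and the
    kernel degenerates to a box filter.

    ``alpha`` is accepted on ``(0, 1]``; values down to 0.01 are meaningful
    (0.01 with the default targets produces the all-ones kernel).
    """
    if not (0.0 < alpha <= 1.0):
        raise InvalidParameterError(f"alpha must lie in (0, 1], got {alpha}")
    c = kernel.coefficients
    peak = c.max()
    if not peak > 0:
        raise InvalidParameterError("kernel maximum must be strictly positive")
    scaled = np.maximum(floor, alpha * max_target * c / peak)
    return Kernel(
        coefficients=scaled,
        half_width=kernel.half_width,
        family=kernel.family,
        alpha=alpha,
        sigma=kernel.sigma,
    )


def gaussian_kernel(
    size: int = 41,
    sigma: float = 5.0,
    max_target: float = 10.0,
    floor: float = 1.0,
) -> Kernel:
    """Isotropic Gaussian kernel scaled to a fixed peak and floored.

    ``exp(-(m**2 + n**2) / (2 * sigma**2))`` on the centered integer grid,
    scaled so the center equals ``max_target`` then lower-limited at
    ``floor``.  The defaults (41 x 41, sigma 5, peak 10, floor 1) give a
    broad, mildly peaked benchmark kernel.
    """
    if not isinstance(size, (int, np.integer)) or size < 1 or size % 2 == 0:
        raise InvalidParameterError(f"size must be an odd positive integer, got {size!r}")
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    w = size // 2
    m = np.arange(-w, w + 1, dtype=float)
    g = np.exp(-(m[:, None] ** 2 + m[None, :] ** 2) / (2.0 * sigma**2))
    scaled = np.maximum(floor, max_target * g)  # center of g is exactly 1
    return Kernel(coefficients=scaled, half_width=int(w), family="gaussian", sigma=float(sigma))


def production_kernel(size: int = 41, alpha: float = 0.1) -> Kernel:
    """The default background-estimation kernel: flattened binomial.

    41 x 41 with ``alpha = 0.1`` balances tracking of smooth illumination
    against suppression of foreground detail.
    """
    if size < 1 or size % 2 == 0:
        raise InvalidParameterError(f"size must be an odd positive integer, got {size!r}")
    return scale_and_flatten(binomial_2d(size // 2), alpha=alpha)
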