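"""Artificial image degradations at levels 1-15.

Three distortions emulate common MRI quality failures, each parameterised
by a single integer level:

* circular (pillbox) blur — level = kernel radius in pixels,
* linear motion blur      — level = streak length in pixels (plus an angle),
* Rician noise            — level = Gaussian sigma as % of the max intensity,

plus a smooth synthetic multiplicative bias field standing in for coil
inhomogeneity.  Blur kernels are normalised to unit sum so mean intensity is
preserved on interior constant regions; boundaries are reflective.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .features import Slice

__all__ = [
    "DegradationSpec",
    "pillbox_kernel",
    "line_kernel",
    "circular_blur",
    "motion_blur",
    "rician_noise",
    "add_rician",
    "bias_field",
    "apply_degradation",
]

KINDS = ("circular_blur", "motion_blur", "rician_noise", "bias_field")


@dataclass(frozen=True)
class DegradationSpec:
    """A reproducible description of one degradation."""

    kind: str
    level: int
    seed: Optional[int] = None       # noise only
    motion_angle: float = 0.0        # motion blur only, degrees

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not 1 <= self.level <= 15:
            raise ValueError(f"level must lie in [1, 15], got {self.level}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _check_level(level: int) -> None:
    if not 1 <= level <= 15:
        raise ValueError(f"level must lie in [1, 15], got {level}")


def pillbox_kernel(radius: int) -> np.ndarray:
    """Normalised circular averaging kernel: constant on the disc of the
    given radius, zero outside, summing to one."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disc = (x * x + y * y) <= radius * radius
    return disc / disc.sum()


def line_kernel(length: int, angle: float = 0.0) -> np.ndarray:
    """Normalised line kernel approximating linear camera motion of the
    given length (pixels) and angle (degrees, anticlockwise from +x)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if length == 1:
        return np.ones((1, 1))
    half = (length - 1) / 2.0
    rad = np.deg2rad(angle)
    # rasterise the centred segment; image rows grow downwards
    t = np.linspace(-half, half, 4 * length)
    cols = np.round(t * np.cos(rad)).astype(int)
    rows = np.round(-t * np.sin(rad)).astype(int)
    r0, c0 = int(np.ceil(half)), int(np.ceil(half))
    kernel = np.zeros((2 * r0 + 1, 2 * c0 + 1))
    kernel[rows + r0, cols + c0] = 1.0
    return kernel / kernel.sum()


def _convolve(slc: Slice, kernel: np.ndarray) -> Slice:
    if max(kernel.shape) >= min(slc.height, slc.width):
        raise ValueError(
            f"kernel {kernel.shape} too large for slice {slc.pixels.shape}"
        )
    blurred = ndimage.convolve(slc.pixels, kernel, mode="reflect")
    return Slice(np.maximum(blurred, 0.0), slc.sequence_tag, slc.spacing)


def circular_blur(slc: Slice, level: int) -> Slice:
    """Convolve with a pillbox kernel of radius ``level`` pixels."""
    _check_level(level)
    if level >= min(slc.height, slc.width) / 2:
        raise ValueError(
            f"blur radius {level} is too large for a {slc.pixels.shape} slice"
        )
    return _convolve(slc, pillbox_kernel(level))


def motion_blur(slc: Slice, level: int, angle: float = 0.0) -> Slice:
    """Convolve with a line kernel of length ``level`` pixels at ``angle``."""
    _check_level(level)
    return _convolve(slc, line_kernel(level, angle))


def add_rician(image: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add Rician noise of scale ``sigma`` to a non-negative image.

    The image is placed in the real channel; independent N(0, sigma^2)
    fields corrupt the real and imaginary channels and the magnitude is
    returned.  On a zero image this reduces to Rayleigh noise with mean
    ``sigma * sqrt(pi / 2)``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.abs(image)
    g1 = rng.normal(0.0, sigma, image.shape)
    g2 = rng.normal(0.0, sigma, image.shape)
    return np.hypot(image + g1, g2)


def rician_noise(slc: Slice, level: int, seed: Optional[int] = None) -> Slice:
    """Rician noise with sigma = (level / 100) x max intensity."""
    _check_level(level)
    if seed is None:
        warnings.warn("rician_noise called without a seed; output is not reproducible")
    rng = np.random.default_rng(seed)
    sigma = (level / 100.0) * float(slc.pixels.max())
    return Slice(add_rician(slc.pixels, sigma, rng), slc.sequence_tag, slc.spacing)


def bias_field(
    slc: Slice,
    level: int,
    profile: str = "gaussian",
    center: Optional[tuple[float, float]] = None,
) -> Slice:
    """Multiply by a smooth, strictly positive intensity-inhomogeneity field.

    ``profile="gaussian"`` uses an off-centre Gaussian bump,
    ``profile="ramp"`` a linear gradient; ``level`` scales the amplitude
    (0 is accepted as the flat-field identity).  The field stays within
    [1 - 0.45, 1 + 0.45] even at level 15.
    """
    if not 0 <= level <= 15:
        raise ValueError(f"level must lie in [0, 15], got {level}")
    h, w = slc.pixels.shape
    amplitude = 0.06 * level
    if profile == "gaussian":
        cy, cx = center if center is not None else (0.35 * h, 0.6 * w)
        yy, xx = np.mgrid[0:h, 0:w]
        s = 0.45 * max(h, w)
        bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    elif profile == "ramp":
        bump = np.linspace(0.0, 1.0, w)[None, :] * np.ones((h, 1))
    else:
        raise ValueError(f"profile must be 'gaussian' or 'ramp', got {profile!r}")
    field = 1.0 + amplitude * (bump - 0.5)
    return Slice(slc.pixels * field, slc.sequence_tag, slc.spacing)


def apply_degradation(slc: Slice, spec: DegradationSpec) -> Slice:
    """Dispatch a DegradationSpec onto a slice."""
    if spec.kind == "circular_blur":
        return circular_blur(slc, spec.level)
    if spec.kind == "motion_blur":
        return motion_blur(slc, spec.level, spec.motion_angle)
    if spec.kind == "rician_noise":
        return rician_noise(slc, spec.level, spec.seed)
    return bias_field(slc, spec.level)
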