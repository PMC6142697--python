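"""Slice normalisation and feature-image extraction.

A test slice is normalised in two steps — foreground extraction and
intensity rescaling to [0, 1] — and two feature images are derived from it:

* the *grayscale* feature image ``I_d`` (the rescaled slice itself), and
* the *local contrast* feature image ``I_c``, the response of a sliding
  range filter (window max minus window min).

Each feature image carries its first moment (mean over foreground pixels by
default), which later serves as a global binarisation threshold.  All arrays
are row-major with 0-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

__all__ = [
    "Slice",
    "ForegroundMask",
    "FeatureImage",
    "EmptySliceError",
    "ZeroDynamicRangeError",
    "extract_foreground",
    "rescale",
    "select_window",
    "local_contrast",
    "first_moment",
]

_MOMENT_TOL = 1e-12


class EmptySliceError(ValueError):
    """No anatomical foreground could be extracted from the slice."""


class ZeroDynamicRangeError(ValueError):
    """The slice is constant; intensity rescaling is undefined."""


@dataclass(frozen=True)
class Slice:
    """A 2-D grayscale MRI slice in arbitrary non-negative scanner units.

    ``sequence_tag`` ("T1", "T2" or "unknown") only affects the default
    volume-level cut-off; ``spacing`` is (row, column) voxel size in mm.
    """

    pixels: np.ndarray
    sequence_tag: str = "unknown"
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError(f"slice must be 2-D, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"slice must be at least 8x8, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("slice intensities must be finite")
        if px.min() < 0:
            raise ValueError("slice intensities must be non-negative")
        if self.sequence_tag not in ("T1", "T2", "unknown"):
            raise ValueError(f"unknown sequence tag {self.sequence_tag!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ForegroundMask:
    """Binary mask of anatomical (non-background) pixels.

    ``n_t``, the foreground pixel count, is the denominator of the
    pixel-wise matching scores.
    """

    mask: np.ndarray
    n_t: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "n_t", int(m.sum()))
        if self.n_t < 1:
            raise EmptySliceError("foreground mask is empty")


@dataclass(frozen=True)
class FeatureImage:
    """A grayscale or local-contrast feature image on [0, 1] with its
    first moment ``mu`` (the binarisation threshold it will supply)."""

    values: np.ndarray
    kind: str  # "grayscale" | "contrast"
    mu: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.kind not in ("grayscale", "contrast"):
            raise ValueError(f"kind must be 'grayscale' or 'contrast', got {self.kind!r}")
        if v.min() < -_MOMENT_TOL or v.max() > 1 + _MOMENT_TOL:
            raise ValueError("feature values must lie in [0, 1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"first moment must lie in [0, 1], got {self.mu}")


def extract_foreground(slc: Slice) -> ForegroundMask:
    """Segment the head region from the air background.

    Moment-preserving (Otsu) thresholding on the raw intensities: for
    images with dark tissue between the air background and bright
    structures, the lower of the two three-class Otsu thresholds separates
    air from tissue (plain Otsu would land in the tissue/bright gap and
    lose the dark interior); degenerate histograms fall back to the
    two-class threshold.  One binary closing pass bridges thin breaks, holes
    are filled, and the largest connected component is kept.  The foreground
    is the whole head, not the brain alone.

    Raises
    ------
    EmptySliceError
        If the slice is all-zero or constant (no two-class structure).
    """
    px = slc.pixels
    if px.max() == px.min():
        raise EmptySliceError(
            "empty slice: constant image has no foreground/background structure"
        )
    try:
        thr = float(threshold_multiotsu(px, classes=3)[0])
    except ValueError:  # fewer than 3 distinct gray levels
        thr = float(threshold_otsu(px))
    raw = px > thr
    if not raw.any():
        raise EmptySliceError("empty slice: no pixels above the Otsu threshold")

    closed = ndimage.binary_closing(raw, structure=np.ones((3, 3), bool))
    filled = ndimage.binary_fill_holes(closed | raw)
    labels, n = ndimage.label(filled)
    if n > 1:
        sizes = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
        filled = labels == (1 + int(np.argmax(sizes)))
    return ForegroundMask(filled)


def rescale(slc: Slice, fg: ForegroundMask, moments_over: str = "foreground") -> FeatureImage:
    """Min-max rescale the slice to [0, 1] (the grayscale feature image).

    The range is taken over the full slice so that the ≈0 air background
    anchors the lower end.  The rescaled slice can then be read as a blurred
    version of an ideal two-valued image.
    """
    px = slc.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        raise ZeroDynamicRangeError("zero dynamic range: constant slice cannot be rescaled")
    values = (px - lo) / (hi - lo)
    return FeatureImage(values, "grayscale", _moment(values, fg, moments_over))


def select_window(height: int, width: int) -> int:
    """Range-filter width from the slice dimensions.

    Widths of 3, 5 and 7 pixels suit images of roughly 250x250, 350x350 and
    450x450 pixels; the nearest size class of ``max(height, width)`` decides.
    Larger windows lose fine detail, smaller ones lose spatial coherence.
    """
    if height < 8 or width < 8:
        raise ValueError("slice must be at least 8x8")
    size = max(height, width)
    if size < 300:
        return 3
    if size < 400:
        return 5
    return 7


def local_contrast(
    gray: FeatureImage,
    fg: ForegroundMask,
    window: int,
    moments_over: str = "foreground",
) -> FeatureImage:
    """Local-range filter response: window max minus window min per pixel.

    Borders use reflective padding so the slice edge itself does not read as
    maximal contrast.  The first moment is computed over the foreground (or
    the full image if ``moments_over="full"``).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    v = gray.values
    if window > min(v.shape):
        raise ValueError(f"window {window} exceeds image size {v.shape}")
    hi = ndimage.maximum_filter(v, size=window, mode="reflect")
    lo = ndimage.minimum_filter(v, size=window, mode="reflect")
    values = hi - lo
    return FeatureImage(values, "contrast", _moment(values, fg, moments_over))


def first_moment(feat: FeatureImage, fg: ForegroundMask) -> float:
    """Arithmetic mean of the feature values over the foreground."""
    return _moment(feat.values, fg, "foreground")


def _moment(values: np.ndarray, fg: ForegroundMask, moments_over: str) -> float:
    if moments_over == "foreground":
        if fg.n_t < 1:
            raise EmptySliceError("cannot take a moment over an empty mask")
        return float(values[fg.mask].mean())
    if moments_over == "full":
        return float(values.mean())
    raise ValueError(f"moments_over must be 'foreground' or 'full', got {moments_over!r}")
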