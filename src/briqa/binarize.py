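"""Moment-thresholded binary feature images.

Crossing the two feature images (grayscale ``I_d``, contrast ``I_c``) with
the two first moments (``mu_d``, ``mu_c``) as global thresholds yields four
binary feature images:

========  ==========  ===========
name      feature     threshold
========  ==========  ===========
FGMG      grayscale   mu_d
FCMG      grayscale   mu_c
FCMC      contrast    mu_c
FGMC      contrast    mu_d
========  ==========  ===========

The comparison is strict (``value > moment``); background pixels are always
dark and excluded from every count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .features import FeatureImage, ForegroundMask

__all__ = ["BinaryFeatureImage", "FourBinaryImages", "threshold", "make_all_four", "edge_pixels"]

# name -> (source feature kind, threshold moment label)
_TABLE = {
    "FGMG": ("grayscale", "mu_d"),
    "FCMG": ("grayscale", "mu_c"),
    "FCMC": ("contrast", "mu_c"),
    "FGMC": ("contrast", "mu_d"),
}


@dataclass(frozen=True)
class BinaryFeatureImage:
    """One of the four binary feature images, with its provenance.

    ``bits`` is restricted to the foreground (background forced dark);
    ``foreground`` is kept so matching scores can be evaluated over the
    anatomical region only.
    """

    bits: np.ndarray
    name: str
    source_kind: str
    threshold_moment: str
    foreground: np.ndarray
    n_bright: int = field(init=False)

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        fg = np.asarray(self.foreground, dtype=bool)
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "foreground", fg)
        object.__setattr__(self, "n_bright", int(bits.sum()))
        if self.name not in _TABLE:
            raise ValueError(f"unknown binary feature image name {self.name!r}")
        kind, moment = _TABLE[self.name]
        if (self.source_kind, self.threshold_moment) != (kind, moment):
            raise ValueError(
                f"{self.name} must pair feature {kind!r} with moment {moment!r}, "
                f"got ({self.source_kind!r}, {self.threshold_moment!r})"
            )
        if bits.shape != fg.shape:
            raise ValueError("bits and foreground shapes differ")
        if np.any(bits & ~fg):
            raise ValueError("background pixels must be dark")


class FourBinaryImages(NamedTuple):
    fgmg: BinaryFeatureImage
    fcmg: BinaryFeatureImage
    fcmc: BinaryFeatureImage
    fgmc: BinaryFeatureImage


def threshold(
    feat: FeatureImage, fg: ForegroundMask, moment: float, name: str
) -> BinaryFeatureImage:
    """Global-threshold a feature image at a first moment.

    A pixel is bright iff it is foreground and its feature value strictly
    exceeds ``moment``; at exact equality it stays dark.
    """
    if name not in _TABLE:
        raise ValueError(f"unknown binary feature image name {name!r}")
    kind, moment_label = _TABLE[name]
    if feat.kind != kind:
        raise ValueError(f"{name} requires a {kind} feature image, got {feat.kind}")
    if not 0.0 <= moment <= 1.0:
        raise ValueError(f"moment must lie in [0, 1], got {moment}")
    if feat.values.shape != fg.mask.shape:
        raise ValueError(
            f"shape mismatch: feature {feat.values.shape} vs mask {fg.mask.shape}"
        )
    bits = fg.mask & (feat.values > moment)
    return BinaryFeatureImage(bits, name, kind, moment_label, fg.mask)


def make_all_four(
    gray: FeatureImage, contrast: FeatureImage, fg: ForegroundMask
) -> FourBinaryImages:
    """Generate FGMG, FCMG, FCMC and FGMC from the two feature images."""
    if gray.kind != "grayscale" or contrast.kind != "contrast":
        raise ValueError("expected (grayscale, contrast) feature images")
    if gray.values.shape != contrast.values.shape:
        raise ValueError("feature image shapes differ")
    mu_d, mu_c = gray.mu, contrast.mu
    return FourBinaryImages(
        fgmg=threshold(gray, fg, mu_d, "FGMG"),
        fcmg=threshold(gray, fg, mu_c, "FCMG"),
        fcmc=threshold(contrast, fg, mu_c, "FCMC"),
        fgmc=threshold(contrast, fg, mu_d, "FGMC"),
    )


def edge_pixels(b: BinaryFeatureImage, connectivity: int = 4) -> np.ndarray:
    """Inner morphological boundary of the bright regions.

    A bright pixel is an edge pixel when at least one neighbour (4- or
    8-neighbourhood; pixels outside the image count as dark) is dark or
    background.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    eroded = ndimage.binary_erosion(b.bits, structure=structure, border_value=0)
    return b.bits & ~eroded
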