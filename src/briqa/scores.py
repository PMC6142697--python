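"""Quality scores and the end-to-end slice/volume pipeline.

Four attribute scores are computed by structurally matching pairs of binary
feature images:

* ``q1`` luminance contrast — edge-pixel matching of (FGMG, FCMG),
* ``q2`` texture            — edge-pixel matching of (FGMC, FCMC),
* ``q3`` texture contrast   — pixel-wise agreement of (FGMC, FCMC),
* ``q4`` lightness          — pixel-wise agreement of (FGMG, FCMG).

Edge-pixel matching counts pixels that are boundary pixels of the bright
regions in *both* images and divides by the larger bright-pixel count.
Pixel-wise matching counts foreground pixels on which the two images agree
(both bright or both dark) and divides by the foreground size ``n_t``.  The
total score is the weighted sum ``Q = w1 q1 + w2 q2 + w3 q3 + w4 q4``; all
five quantities lie in [0, 1], with 1 attained by an ideal two-valued image.

Volume-level quality is the mean of the per-slice totals, compared against a
sequence-specific cut-off (0.40 for T1, 0.45 for T2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binarize import BinaryFeatureImage, edge_pixels, make_all_four
from .config import Config, Weights
from .features import Slice, extract_foreground, local_contrast, rescale, select_window

__all__ = [
    "Weights",
    "QualityReport",
    "VolumeReport",
    "luminance_contrast",
    "texture",
    "texture_contrast",
    "lightness",
    "total",
    "score_slice",
    "score_volume",
    "aggregate",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class QualityReport:
    """Per-slice quality scores plus the quantities they were derived from."""

    q1: float
    q2: float
    q3: float
    q4: float
    Q: float
    slice_index: int = 0
    n_t: int = 0
    mu_d: float = float("nan")
    mu_c: float = float("nan")
    window: int = 0

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "q4", "Q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict:
        return {
            "slice_index": self.slice_index,
            "n_t": self.n_t,
            "mu_d": self.mu_d,
            "mu_c": self.mu_c,
            "q1": self.q1,
            "q2": self.q2,
            "q3": self.q3,
            "q4": self.q4,
            "Q": self.Q,
        }


@dataclass(frozen=True)
class VolumeReport:
    """Per-volume aggregate: slice reports, attribute means, pass/fail."""

    per_slice: tuple[QualityReport, ...]
    cutoff: float
    mean_q1: float = field(init=False)
    mean_q2: float = field(init=False)
    mean_q3: float = field(init=False)
    mean_q4: float = field(init=False)
    mean_Q: float = field(init=False)
    passes: bool = field(init=False)

    def __post_init__(self) -> None:
        reports = tuple(self.per_slice)
        if not reports:
            raise ValueError("a volume needs at least one slice report")
        object.__setattr__(self, "per_slice", reports)
        for attr in ("q1", "q2", "q3", "q4", "Q"):
            mean = float(np.mean([getattr(r, attr) for r in reports]))
            object.__setattr__(self, f"mean_{attr}", mean)
        object.__setattr__(self, "passes", bool(self.mean_Q >= self.cutoff))

    def to_frame(self) -> pd.DataFrame:
        """One row per slice: index, n_t, moments, q1-q4, Q."""
        return pd.DataFrame([r.as_dict() for r in self.per_slice])

    def summary(self) -> dict:
        return {
            "n_slices": len(self.per_slice),
            "mean_q1": self.mean_q1,
            "mean_q2": self.mean_q2,
            "mean_q3": self.mean_q3,
            "mean_q4": self.mean_q4,
            "mean_Q": self.mean_Q,
            "cutoff": self.cutoff,
            "passes": self.passes,
        }


def _check_pair(a: BinaryFeatureImage, b: BinaryFeatureImage, kind: str) -> None:
    if a.source_kind != kind or b.source_kind != kind:
        raise ValueError(
            f"expected a pair of {kind}-derived binary images, "
            f"got ({a.source_kind}, {b.source_kind})"
        )
    if a.bits.shape != b.bits.shape:
        raise ValueError("binary image shapes differ")


def _edge_match(
    a: BinaryFeatureImage,
    b: BinaryFeatureImage,
    connectivity: int,
    edge_denominator: bool,
) -> float:
    ea, eb = edge_pixels(a, connectivity), edge_pixels(b, connectivity)
    numerator = int(np.sum(ea & eb))
    if edge_denominator:
        denominator = max(int(ea.sum()), int(eb.sum()))
    else:
        denominator = max(a.n_bright, b.n_bright)
    if denominator == 0:
        warnings.warn(
            "both bright sets are empty; no supra-threshold structure to match "
            "(score set to 0)",
            stacklevel=3,
        )
        return 0.0
    return numerator / denominator


def luminance_contrast(
    fgmg: BinaryFeatureImage,
    fcmg: BinaryFeatureImage,
    connectivity: int = 4,
    edge_denominator: bool = False,
) -> float:
    """q1: edge-pixel matching of the two grayscale-derived binary images."""
    _check_pair(fgmg, fcmg, "grayscale")
    return _edge_match(fgmg, fcmg, connectivity, edge_denominator)


def texture(
    fgmc: BinaryFeatureImage,
    fcmc: BinaryFeatureImage,
    connectivity: int = 4,
    edge_denominator: bool = False,
) -> float:
    """q2: edge-pixel matching of the two contrast-derived binary images."""
    _check_pair(fgmc, fcmc, "contrast")
    return _edge_match(fgmc, fcmc, connectivity, edge_denominator)


def _pixelwise_agreement(a: BinaryFeatureImage, b: BinaryFeatureImage, n_t: int) -> float:
    if n_t < 1:
        raise ValueError(f"foreground pixel count must be >= 1, got {n_t}")
    agree = int(np.sum((a.bits == b.bits) & a.foreground))
    return agree / n_t


def texture_contrast(
    fgmc: BinaryFeatureImage, fcmc: BinaryFeatureImage, n_t: int
) -> float:
    """q3: fraction of foreground pixels on which FGMC and FCMC agree.

    Both bright and both dark count as agreement; for an ideal image the
    two moments coincide, the pair is identical, and q3 = 1.
    """
    _check_pair(fgmc, fcmc, "contrast")
    return _pixelwise_agreement(fgmc, fcmc, n_t)


def lightness(fgmg: BinaryFeatureImage, fcmg: BinaryFeatureImage, n_t: int) -> float:
    """q4: fraction of foreground pixels on which FGMG and FCMG agree."""
    _check_pair(fgmg, fcmg, "grayscale")
    return _pixelwise_agreement(fgmg, fcmg, n_t)


def total(q1: float, q2: float, q3: float, q4: float, weights: Weights | None = None) -> float:
    """Weighted total quality score Q."""
    w = weights or Weights()
    for name, q in zip(("q1", "q2", "q3", "q4"), (q1, q2, q3, q4)):
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {q}")
    return w.w_q1 * q1 + w.w_q2 * q2 + w.w_q3 * q3 + w.w_q4 * q4


def score_slice(slc: Slice, config: Optional[Config] = None, slice_index: int = 0) -> QualityReport:
    """Run the full pipeline on one slice.

    Foreground extraction, [0, 1] rescaling, range-filter contrast feature,
    the four binary feature images, the four matching scores and the
    weighted total.  Deterministic for a fixed input and configuration.
    """
    cfg = config or Config()
    fg = extract_foreground(slc)
    gray = rescale(slc, fg, cfg.moments_over)
    window = cfg.window or select_window(slc.height, slc.width)
    contrast = local_contrast(gray, fg, window, cfg.moments_over)
    four = make_all_four(gray, contrast, fg)

    q1 = luminance_contrast(four.fgmg, four.fcmg, cfg.edge_connectivity, cfg.edge_denominator)
    q2 = texture(four.fgmc, four.fcmc, cfg.edge_connectivity, cfg.edge_denominator)
    q3 = texture_contrast(four.fgmc, four.fcmc, fg.n_t)
    q4 = lightness(four.fgmg, four.fcmg, fg.n_t)
    Q = total(q1, q2, q3, q4, cfg.weights)
    return QualityReport(
        q1=q1, q2=q2, q3=q3, q4=q4, Q=Q,
        slice_index=slice_index, n_t=fg.n_t,
        mu_d=gray.mu, mu_c=contrast.mu, window=window,
    )


def aggregate(reports: Sequence[QualityReport], cutoff: float) -> VolumeReport:
    """Aggregate per-slice reports into a volume report."""
    return VolumeReport(per_slice=tuple(reports), cutoff=cutoff)


def score_volume(
    slices: Sequence[Slice],
    cutoff: Optional[float] = None,
    config: Optional[Config] = None,
) -> VolumeReport:
    """Score every slice and aggregate.

    The pass/fail cut-off defaults to the sequence-specific value taken from
    the first slice's tag (0.40 for T1/unknown, 0.45 for T2).
    """
    if not slices:
        raise ValueError("cannot score an empty volume")
    cfg = config or Config()
    if cutoff is None:
        cutoff = cfg.cutoff_for(slices[0].sequence_tag)
    reports = [score_slice(s, cfg, slice_index=i) for i, s in enumerate(slices)]
    return aggregate(reports, cutoff)
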