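"""Synthetic two-tissue-class brain-slice phantom.

The phantom emulates the structure the quality metric assumes: a bright,
convoluted rim of high edge density (cortical gray matter and structure
boundaries) wrapped around darker, smoothly varying interior tissue (white
matter and the rest), on a zero air background.  Because the generator also
returns its ground-truth foreground mask and tissue labels, every pipeline
stage can be tested without clinical data.

Gyri-like convolution of the rim is produced by low-frequency sinusoidal
perturbation of the outer ellipse boundary plus a higher-frequency
perturbation of the rim's inner boundary.  Generation is fully deterministic
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .features import ForegroundMask, Slice

__all__ = ["PhantomSpec", "generate", "generate_volume", "ideal_spec"]

BACKGROUND, INTERIOR, RIM = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic slice.

    Default intensities are T2-like (background < interior < rim); a T1-like
    phantom can invert the rim/interior ordering as long as the background
    stays darkest.  ``rim_thickness`` is the mean radial width of the bright
    band in pixels.
    """

    height: int = 256
    width: int = 256
    rim_intensity: float = 1.0
    interior_intensity: float = 0.12
    background_intensity: float = 0.0
    rim_thickness: int = 3
    n_interior_blobs: int = 6
    seed: int = 0
    sequence_tag: str = "T2"

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom canvas must be at least 16x16")
        if self.rim_thickness < 1:
            raise ValueError("rim_thickness must be >= 1")
        if self.background_intensity < 0:
            raise ValueError("background intensity must be >= 0")
        lo, hi = sorted((self.interior_intensity, self.rim_intensity))
        if not self.background_intensity < hi:
            raise ValueError("tissue intensities must exceed the background")
        if lo < self.background_intensity:
            raise ValueError("tissue intensities must not fall below the background")


def ideal_spec(height: int = 256, width: int = 256, seed: int = 0) -> PhantomSpec:
    """Spec for an ideal two-valued {0, 1} phantom (rim 1, interior 0,
    no blobs) — the undistorted regime in which all binary feature pairs
    coincide and the pixel-wise scores are exactly 1."""
    return PhantomSpec(
        height=height,
        width=width,
        rim_intensity=1.0,
        interior_intensity=0.0,
        background_intensity=0.0,
        n_interior_blobs=0,
        seed=seed,
    )


def generate(
    spec: PhantomSpec, scale: float = 1.0
) -> tuple[Slice, ForegroundMask, np.ndarray]:
    """Generate one phantom slice.

    Returns the slice, its ground-truth head mask and a label image
    (0 background, 1 interior, 2 rim).  ``scale`` shrinks the head ellipse
    (used for through-volume geometry); the wiggle phases depend only on the
    seed, so scaled slices vary smoothly.
    """
    if not 0.1 <= scale <= 1.0:
        raise ValueError(f"scale must lie in (0.1, 1], got {scale}")
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    # outer boundary: ellipse with two low-frequency harmonics (head outline)
    a = 0.40 * h * scale
    b = 0.42 * w * scale
    outer_eps = (0.025, 0.02)
    if a * (1 + sum(outer_eps)) >= h / 2 or b * (1 + sum(outer_eps)) >= w / 2:
        raise ValueError("phantom geometry does not fit the canvas")
    phases = rng.uniform(0, 2 * np.pi, size=4)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / a, (xx - cx) / b
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    rho_out = (
        1.0
        + outer_eps[0] * np.sin(7 * theta + phases[0])
        + outer_eps[1] * np.sin(11 * theta + phases[1])
    )
    head = r <= rho_out

    # inner rim boundary: thicker wiggle at higher frequency (gyral folds)
    t = spec.rim_thickness / ((a + b) / 2.0)
    # inner wiggle amplitudes keep the band at least ~60% of its mean
    # thickness everywhere, so the rim never pinches apart on the grid
    rho_in = rho_out - t * (
        1.0
        + 0.25 * np.sin(19 * theta + phases[2])
        + 0.15 * np.sin(29 * theta + phases[3])
    )
    rim = head & (r > rho_in)
    interior = head & ~rim

    img = np.full((h, w), float(spec.background_intensity))
    interior_vals = np.full((h, w), float(spec.interior_intensity))
    bright_structures = np.zeros((h, w), dtype=bool)
    if spec.n_interior_blobs > 0:
        # thin bright curvilinear structures (sulcal CSF / structure
        # boundaries): elliptical ring segments about rim_thickness wide,
        # near the bright tissue intensity, over a mild smooth shading bump
        span = abs(spec.rim_intensity - spec.interior_intensity)
        for _ in range(spec.n_interior_blobs):
            bt = rng.uniform(0, 2 * np.pi)
            br = rng.uniform(0.0, 0.45)
            by, bx = cy + br * a * np.sin(bt), cx + br * b * np.cos(bt)
            ba = rng.uniform(0.12, 0.35) * a
            bb = rng.uniform(0.12, 0.35) * b
            ang = rng.uniform(0, np.pi)
            u = (yy - by) * np.cos(ang) - (xx - bx) * np.sin(ang)
            v = (yy - by) * np.sin(ang) + (xx - bx) * np.cos(ang)
            rho_b = np.hypot(u / ba, v / bb)
            half = spec.rim_thickness / (ba + bb)  # ring half-width in rho units
            ring = np.abs(rho_b - 1.0) <= half
            # keep an angular arc of the ring, not the full ellipse
            arc_lo = rng.uniform(0, 2 * np.pi)
            arc_len = rng.uniform(0.6, 1.6) * np.pi
            arc_angle = np.mod(np.arctan2(u, v) - arc_lo, 2 * np.pi)
            ring &= arc_angle <= arc_len
            level = spec.interior_intensity + rng.uniform(0.75, 1.0) * span
            interior_vals[ring] = level
            bright_structures |= ring
        st = rng.uniform(0, 2 * np.pi)
        sy, sx = cy + 0.3 * a * np.sin(st), cx + 0.3 * b * np.cos(st)
        sig = 0.5 * min(a, b)
        shade = 0.05 * span * np.exp(
            -(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * sig * sig))
        )
        # smooth stochastic texture: tissue intensities are continuous, not
        # two atoms, so moments never sit on a knife edge of the histogram
        texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
        texture *= 0.10 * span / texture.std()
        lo = spec.background_intensity + 0.1 * (
            spec.interior_intensity - spec.background_intensity
        )
        interior_vals = np.clip(
            interior_vals + shade + texture, lo, spec.rim_intensity
        )
    img[interior] = interior_vals[interior]
    img[rim] = spec.rim_intensity

    labels = np.zeros((h, w), dtype=np.uint8)
    labels[interior] = INTERIOR
    labels[rim | (bright_structures & interior)] = RIM  # bright tissue class
    slc = Slice(img, sequence_tag=spec.sequence_tag)
    return slc, ForegroundMask(head), labels


def generate_volume(spec: PhantomSpec, n_slices: int) -> list[Slice]:
    """A stack of phantom slices with smoothly varying head size.

    The head ellipse scales as a half-sine through the volume, so the
    mid-volume slice has the largest foreground area, mimicking axial
    coverage from skull base to vertex.  All slices share the seed-derived
    wiggle phases and blob layout, so the anatomy varies smoothly with the
    geometry.  A single-slice volume equals ``generate(spec)``.
    """
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    slices = []
    for i in range(n_slices):
        scale = 0.55 + 0.45 * np.sin(np.pi * (i + 1) / (n_slices + 1))
        slc, _, _ = generate(replace(spec, seed=spec.seed), scale=scale)
        slices.append(slc)
    return slices
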