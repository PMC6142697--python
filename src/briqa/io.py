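"""Reading and writing slices, volumes and reports.

NIfTI volumes are handled through nibabel (slices extracted along a chosen
axis, default the last), plain 2-D images (PNG/TIFF) through imageio for
fixtures and debug dumps.  Score reports go out as CSV (one row per slice)
and JSON (volume summary).  Small negative intensities from interpolation
are clipped to zero with a warning, since the metric assumes magnitude data.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .features import Slice
from .scores import VolumeReport

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_image",
    "write_image",
    "write_slice_csv",
    "write_volume_json",
]


def _clip_negatives(data: np.ndarray, source: str) -> np.ndarray:
    if data.min() < 0:
        warnings.warn(f"{source}: negative intensities clipped to 0 (magnitude data assumed)")
        data = np.clip(data, 0, None)
    return data


def read_nifti(
    path: str | Path,
    axis: int = -1,
    sequence_tag: str = "unknown",
) -> list[Slice]:
    """Load a NIfTI volume as a list of 2-D slices along ``axis``."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D volume, got shape {data.shape}")
    data = _clip_negatives(data, str(path))
    data = np.moveaxis(data, axis, 0)

    zooms = img.header.get_zooms()[:3]
    in_plane = tuple(z for i, z in enumerate(zooms) if i != (axis % 3)) or (1.0, 1.0)
    spacing = (float(in_plane[0]), float(in_plane[-1]))
    return [Slice(plane, sequence_tag, spacing) for plane in data]


def write_nifti(slices: Sequence[Slice], path: str | Path) -> None:
    """Stack slices along the last axis and save as NIfTI."""
    if not slices:
        raise ValueError("no slices to write")
    vol = np.stack([s.pixels for s in slices], axis=-1)
    sp = slices[0].spacing
    affine = np.diag([sp[0], sp[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def read_image(path: str | Path, sequence_tag: str = "unknown") -> Slice:
    """Load a 2-D PNG/TIFF image as a slice (RGB collapsed to luminance)."""
    data = np.asarray(iio.imread(str(path)), dtype=float)
    if data.ndim == 3:
        data = data[..., :3].mean(axis=-1)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {data.shape}")
    return Slice(_clip_negatives(data, str(path)), sequence_tag)


def write_image(slc: Slice | np.ndarray, path: str | Path) -> None:
    """Save a slice or array as a 16-bit PNG / TIFF, min-max scaled."""
    data = slc.pixels if isinstance(slc, Slice) else np.asarray(slc, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    scaled = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    iio.imwrite(str(path), (scaled * 65535).astype(np.uint16))


def write_slice_csv(report: VolumeReport, path: str | Path) -> None:
    """Per-slice CSV: slice_index, n_t, mu_d, mu_c, q1-q4, Q."""
    report.to_frame().to_csv(str(path), index=False)


def write_volume_json(
    report: VolumeReport, path: str | Path, extra: Optional[dict] = None
) -> None:
    """Volume summary JSON (means, cutoff, pass/fail), plus any extras."""
    payload = report.summary()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
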