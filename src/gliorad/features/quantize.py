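"""Gray-level quantization of a masked region of interest.

Texture matrices operate on integer gray levels 1..B obtained by min-max
binning of the raw intensities inside the ROI:

    level(v) = min(B, floor((v - min) / (max - min) * B) + 1)

A constant-intensity ROI maps every voxel to level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EmptyRegionError(ValueError):
    """Raised when a requested region has no voxels in the mask."""


@dataclass(frozen=True)
class QuantizedROI:
    """A quantized region cropped to its bounding box.

    Attributes
    ----------
    levels : int ndarray, levels 1..bins inside the ROI, 0 outside.
    mask : bool ndarray, True inside the ROI.
    values : float ndarray, raw intensities (undefined outside the ROI).
    spacing : voxel spacing in mm per axis.
    bins : number of gray levels B.
    """

    levels: np.ndarray
    mask: np.ndarray
    values: np.ndarray
    spacing: tuple[float, float, float]
    bins: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def roi_values(self) -> np.ndarray:
        """Raw intensities of in-ROI voxels as a flat array."""
        return self.values[self.mask]

    @property
    def roi_levels(self) -> np.ndarray:
        """Quantized levels of in-ROI voxels as a flat array."""
        return self.levels[self.mask]


def quantize_values(values: np.ndarray, bins: int) -> np.ndarray:
    """Min-max quantize a flat array of intensities into levels 1..bins."""
    values = np.asarray(values, dtype=float)
    vmin = values.min()
    vmax = values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    lv = np.floor((values - vmin) / (vmax - vmin) * bins).astype(np.int64) + 1
    return np.minimum(lv, bins)


def quantize_roi(
    volume: np.ndarray,
    mask: np.ndarray,
    region_code: int,
    bins: int = 16,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    region_name: str | None = None,
    subject_id: str | None = None,
) -> QuantizedROI:
    """Extract and quantize the ROI ``mask == region_code`` from ``volume``.

    The result is cropped to the ROI bounding box; voxels outside the ROI
    have level 0 and never influence downstream features.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    region = mask == region_code
    if not region.any():
        who = f" of subject {subject_id}" if subject_id else ""
        label = region_name or str(region_code)
        raise EmptyRegionError(f"region {label}{who} has no voxels in the mask")

    slices = tuple(
        slice(idx.min(), idx.max() + 1) for idx in np.nonzero(region)
    )
    sub_mask = region[slices]
    sub_vals = volume[slices]
    if not np.isfinite(sub_vals[sub_mask]).all():
        raise ValueError("non-finite intensities inside the ROI")

    levels = np.zeros(sub_mask.shape, dtype=np.int64)
    levels[sub_mask] = quantize_values(sub_vals[sub_mask], bins)
    return QuantizedROI(
        levels=levels,
        mask=sub_mask,
        values=sub_vals,
        spacing=tuple(float(s) for s in spacing),
        bins=bins,
    )
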