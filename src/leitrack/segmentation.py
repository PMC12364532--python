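"""Binary plant-mask extraction from a frame.

The plant is separated from the dark soil background by thresholding a
vegetation index, then cleaned by region-of-interest cropping, hole filling
and small-object removal.  The default index is excess green,
``ExG = 2G - R - B`` on channels scaled to [0, 1] — a standard choice for
green-on-soil segmentation; any per-pixel index function with the same
signature may be plugged in instead.

Thresholds are deliberately *per-series constants* tuned once on an exemplary
image, not auto-estimated per frame: the lighting in a time-lapse chamber is
constant and a fixed threshold keeps the measurement comparable across the
whole series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import morphology

from .io_timelapse import Frame, FrameMeta


@dataclass(frozen=True)
class SegmentationParams:
    """Per-series segmentation constants.

    Parameters
    ----------
    threshold
        Vegetation-index cut; pixels with (clipped) index strictly above it
        are plant.
    max_value
        Index clipping ceiling applied before thresholding.
    size
        Minimum connected-component area in px; smaller specks are removed.
    roi
        Optional ``(row0, col0, height, width)`` rectangle; everything outside
        is background.  ``None`` keeps the full frame.
    """

    threshold: float = 0.3
    max_value: float = 2.0
    size: int = 50
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.threshold < self.max_value:
            raise ValueError(
                f"threshold ({self.threshold}) must be < max_value ({self.max_value})"
            )
        if self.size < 0:
            raise ValueError(f"size must be >= 0, got {self.size}")
        if self.roi is not None:
            r0, c0, h, w = self.roi
            if h < 0 or w < 0:
                raise ValueError(f"roi height/width must be >= 0, got {self.roi}")


@dataclass
class BinaryMask:
    """Boolean plant/background grid with provenance and QC flags."""

    grid: np.ndarray
    source: FrameMeta | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError(f"mask grid must be 2-D, got shape {self.grid.shape}")

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return not self.grid.any()


def excess_green(frame: Frame | np.ndarray) -> np.ndarray:
    """Per-pixel excess-green index, ``2G - R - B`` on [0, 1] channels.

    Output range is [-2, 2]: pure green maps to 2, any gray to 0,
    pure red or blue to -1.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    rgb = pixels.astype(np.float64) / 255.0
    return 2.0 * rgb[:, :, 1] - rgb[:, :, 0] - rgb[:, :, 2]


def threshold_mask(
    index_grid: np.ndarray,
    params: SegmentationParams,
    source: FrameMeta | None = None,
) -> BinaryMask:
    """Mask true where ``min(index, max_value) > threshold``."""
    grid = np.minimum(np.asarray(index_grid, dtype=np.float64), params.max_value)
    return BinaryMask(grid > params.threshold, source=source)


def clean_mask(mask: BinaryMask, params: SegmentationParams) -> BinaryMask:
    """Crop to ROI, fill interior holes, drop components smaller than ``size``.

    Components use 8-connectivity; holes are interior background regions in
    the dual 4-connected sense.  Every surviving component is kept — in side
    view the rosette legitimately fragments into several leaves, so there is
    no largest-component shortcut (pass ``size`` high enough to kill noise
    instead).
    """
    grid = mask.grid
    if params.roi is not None:
        r0, c0, h, w = params.roi
        if r0 < 0 or c0 < 0 or r0 + h > grid.shape[0] or c0 + w > grid.shape[1]:
            raise ValueError(
                f"roi {params.roi} exceeds frame bounds {grid.shape}"
            )
        cropped = np.zeros_like(grid)
        cropped[r0:r0 + h, c0:c0 + w] = grid[r0:r0 + h, c0:c0 + w]
        grid = cropped
    else:
        grid = grid.copy()
    grid = ndimage.binary_fill_holes(grid)
    if params.size > 0:
        # drop components with area < size, i.e. area <= size - 1
        grid = morphology.remove_small_objects(grid, max_size=params.size - 1, connectivity=2)
    return BinaryMask(grid, source=mask.source, flags=mask.flags)


def segment_plant(
    frame: Frame,
    params: SegmentationParams,
    index_fn: Callable[[Frame], np.ndarray] = excess_green,
) -> BinaryMask:
    """Full segmentation: vegetation index -> threshold -> clean.

    An empty result is *flagged* (``"empty"``), not an error, so a batch
    caller can skip the time point and keep going.
    """
    mask = threshold_mask(index_fn(frame), params, source=frame.meta)
    mask = clean_mask(mask, params)
    if mask.is_empty:
        mask.flags = mask.flags + ("empty",)
    return mask


def write_mask_png(mask: BinaryMask, path: str | Path) -> Path:
    """Dump a mask as a 0/255 grayscale PNG for visual audit."""
    path = Path(path)
    iio.imwrite(path, (mask.grid.astype(np.uint8) * 255))
    return path
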