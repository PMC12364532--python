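"""Pixel-space shape measurements on binary plant masks.

Top view: the rosette silhouette is summarized by its *equal-moment ellipse*
— the ellipse whose second-order central moments match those of the mask.
Its full axes are ``4 * sqrt(eigenvalue)`` of the coordinate covariance
matrix, a convention under which a filled disc of radius R reports a major
and minor axis of exactly 2R.  This fit is deterministic and contour-free.

Side view: plant height is the distance in rows from a fixed soil reference
line (``line_position``, an image row) up to the highest plant pixel.  Rows
follow the image convention: row 0 at the top, increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import BinaryMask

#: eigenvalues below this (px^2) are treated as a degenerate (collinear) axis
_DEGENERATE_EPS = 1e-12


class MeasurementError(ValueError):
    """A geometric measurement is undefined for this mask (e.g. empty)."""


@dataclass(frozen=True)
class MaskMoments:
    """Pixel count, centroid and normalized second central moments (px^2)."""

    n: int
    centroid: tuple[float, float]  # (row, col)
    mu20: float  # variance of rows
    mu02: float  # variance of cols
    mu11: float  # row-col covariance


@dataclass(frozen=True)
class EllipseFit:
    """Equal-moment ellipse of a mask.

    ``orientation_rad`` is the angle of the major axis measured from the
    column axis, counter-clockwise with y pointing up (image rows negated),
    wrapped into (-pi/2, pi/2].
    """

    centroid: tuple[float, float]
    major_axis_px: float
    minor_axis_px: float
    orientation_rad: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class HeightMeasurement:
    """Plant height above the soil line, in pixel rows."""

    height_px: int
    top_row: int
    line_position: int
    flags: tuple[str, ...] = ()


def mask_moments(mask: BinaryMask) -> MaskMoments:
    """Centroid and normalized second central moments of the true pixels.

    Pixel centers sit at integer coordinates; moments are divided by the
    pixel count, so ``mu20``/``mu02`` are coordinate variances in px^2.
    """
    coords = np.argwhere(mask.grid)
    if coords.shape[0] == 0:
        raise MeasurementError("cannot compute moments of an empty mask")
    rows = coords[:, 0].astype(np.float64)
    cols = coords[:, 1].astype(np.float64)
    n = coords.shape[0]
    r0, c0 = rows.mean(), cols.mean()
    dr, dc = rows - r0, cols - c0
    return MaskMoments(
        n=n,
        centroid=(float(r0), float(c0)),
        mu20=float(dr @ dr) / n,
        mu02=float(dc @ dc) / n,
        mu11=float(dr @ dc) / n,
    )


def fit_ellipse(mask: BinaryMask) -> EllipseFit:
    """Fit the equal-moment ellipse: axes are 4*sqrt(covariance eigenvalues).

    A mask whose pixels are collinear yields ``minor_axis_px == 0`` and the
    ``"degenerate"`` flag instead of an error, because a fully flattened
    rosette silhouette is a legitimate (if extreme) observation.
    """
    m = mask_moments(mask)
    cov = np.array([[m.mu20, m.mu11], [m.mu11, m.mu02]])
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = float(eigvals[0]), float(eigvals[1])
    lam_minor = max(lam_minor, 0.0)
    flags: tuple[str, ...] = ()
    if lam_minor <= _DEGENERATE_EPS:
        lam_minor = 0.0
        flags = ("degenerate",)
    major = 4.0 * math.sqrt(lam_major)
    minor = 4.0 * math.sqrt(lam_minor)
    if lam_major <= _DEGENERATE_EPS:
        orientation = 0.0  # single pixel: no direction
    else:
        v_row, v_col = eigvecs[0, 1], eigvecs[1, 1]  # eigenvector of lam_major
        orientation = math.atan2(-v_row, v_col)  # y-up angle vs column axis
        if orientation <= -math.pi / 2:
            orientation += math.pi
        elif orientation > math.pi / 2:
            orientation -= math.pi
    return EllipseFit(
        centroid=m.centroid,
        major_axis_px=major,
        minor_axis_px=minor,
        orientation_rad=orientation,
        flags=flags,
    )


def measure_height(
    mask: BinaryMask, line_position: int, clip_below_line: bool = True
) -> HeightMeasurement:
    """Height in rows from the soil line up to the highest plant pixel.

    With ``clip_below_line`` (the default) pixels at or below the soil line
    — pot rim, soil reflections — are ignored entirely; a mask living wholly
    below the line then reports height 0 with the ``"below_line"`` flag.
    """
    if mask.is_empty:
        raise MeasurementError("cannot measure height of an empty mask")
    n_rows = mask.grid.shape[0]
    if not 0 <= line_position < n_rows:
        raise ValueError(
            f"line_position {line_position} outside image rows [0, {n_rows})"
        )
    rows = np.flatnonzero(mask.grid.any(axis=1))
    if clip_below_line:
        rows = rows[rows < line_position]
    if rows.size == 0:
        return HeightMeasurement(
            height_px=0,
            top_row=line_position,
            line_position=line_position,
            flags=("below_line",),
        )
    top_row = int(rows.min())
    return HeightMeasurement(
        height_px=max(0, line_position - top_row),
        top_row=top_row,
        line_position=line_position,
    )
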