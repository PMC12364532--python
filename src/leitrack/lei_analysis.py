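"""Leaf elevation index (LEI) computation and group time-course aggregation.

The rosette is idealized as a cylinder: the top-view ellipse gives its
radius r (mean of the major and minor axes, halved), the side view gives
its height h above the soil, and

    LEI = arctan(h / r) * 180 / pi      (degrees, in [0, 90))

summarizes the leaf elevation status of the whole plant.  A flat rosette
scores near 0; strongly hyponastic leaves push the score toward 90.

Group trajectories report, per time point, the mean LEI over plants minus
the group mean at treatment onset (so the curve starts at exactly 0), with
the standard error of the mean as the spread.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry, segmentation
from .io_timelapse import FrameLoadError, SeriesIndex, View, load_frame

logger = logging.getLogger(__name__)

GROUP_COLUMNS = ("label", "timestamp_min", "mean_dlei_deg", "sem_deg", "n")


class CalibrationError(ValueError):
    pass


class NormalizationError(ValueError):
    """No measurement exists at the onset time point; the zero is undefined."""


@dataclass(frozen=True)
class Calibration:
    """mm-per-pixel conversion factors, one per camera."""

    mm_per_px_top: float
    mm_per_px_side: float

    def __post_init__(self) -> None:
        for name in ("mm_per_px_top", "mm_per_px_side"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise CalibrationError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class LEIRecord:
    """Calibrated cylinder geometry and LEI for one plant at one time point."""

    plant_id: str
    timestamp_min: int
    major_px: float
    minor_px: float
    height_px: float
    mm_per_px_top: float
    mm_per_px_side: float
    h_mm: float
    r_mm: float
    lei_deg: float


@dataclass
class GroupTimeCourse:
    """Normalized mean +/- SEM LEI trajectory for one genotype x treatment group."""

    label: str
    timepoints: list[int]
    mean_dlei: list[float]
    sem: list[float]
    n: list[int]
    flags: tuple[str, ...] = ()


def calibrate(px_distance: float, mm_distance: float) -> float:
    """mm-per-pixel factor from a length standard photographed in the scene."""
    if px_distance <= 0 or mm_distance <= 0:
        raise CalibrationError(
            f"distances must be > 0, got {px_distance} px / {mm_distance} mm"
        )
    return mm_distance / px_distance


def radius_from_axes(major_mm: float, minor_mm: float) -> float:
    """Cylinder radius: mean of the two ellipse axes taken as the diameter.

    r = ((major + minor) / 2) / 2
    """
    if not major_mm >= minor_mm >= 0:
        raise ValueError(f"need major >= minor >= 0, got ({major_mm}, {minor_mm})")
    if major_mm == 0 and minor_mm == 0:
        raise ValueError("degenerate plant: both ellipse axes are zero")
    return (major_mm + minor_mm) / 4.0


def compute_lei(h_mm: float, r_mm: float) -> float:
    """LEI = arctan(h / r) * 180 / pi, in degrees within [0, 90)."""
    if r_mm <= 0:
        raise ValueError(f"radius must be > 0, got {r_mm}")
    if h_mm < 0:
        raise ValueError(f"height must be >= 0, got {h_mm}")
    return math.degrees(math.atan(h_mm / r_mm))


def build_records(
    series: SeriesIndex,
    params: segmentation.SegmentationParams,
    line_position: int,
    cal: Calibration,
    params_side: segmentation.SegmentationParams | None = None,
    clip_below_line: bool = True,
) -> list[LEIRecord]:
    """Measure every complete top/side pair of a series.

    Per pair: segment both views, fit the top-view moment ellipse, measure
    side-view height above the soil line, convert with the view-specific
    calibration, compute LEI.  A pair that fails at any stage (unreadable
    file, empty mask, degenerate geometry) is logged and skipped; the batch
    never aborts mid-series.
    """
    if params_side is None:
        params_side = params
    records: list[LEIRecord] = []
    if not series.complete:
        logger.warning("series contains no complete top/side pairs")
        return records
    for plant_id, t in series.complete:
        views = series.pairs[(plant_id, t)]
        try:
            top_mask = segmentation.segment_plant(load_frame(views[View.TOP]), params)
            side_mask = segmentation.segment_plant(
                load_frame(views[View.SIDE]), params_side
            )
            if top_mask.is_empty or side_mask.is_empty:
                which = "top" if top_mask.is_empty else "side"
                logger.warning(
                    "skip (%s, t=%d): empty %s-view mask", plant_id, t, which
                )
                continue
            ellipse = geometry.fit_ellipse(top_mask)
            height = geometry.measure_height(
                side_mask, line_position, clip_below_line=clip_below_line
            )
            major_mm = ellipse.major_axis_px * cal.mm_per_px_top
            minor_mm = ellipse.minor_axis_px * cal.mm_per_px_top
            h_mm = height.height_px * cal.mm_per_px_side
            r_mm = radius_from_axes(major_mm, minor_mm)
            lei_deg = compute_lei(h_mm, r_mm)
            logger.info(
                "measured (%s, t=%d): h=%.2f mm r=%.2f mm lei=%.2f deg",
                plant_id, t, h_mm, r_mm, lei_deg,
            )
            records.append(
                LEIRecord(
                    plant_id=plant_id,
                    timestamp_min=t,
                    major_px=ellipse.major_axis_px,
                    minor_px=ellipse.minor_axis_px,
                    height_px=float(height.height_px),
                    mm_per_px_top=cal.mm_per_px_top,
                    mm_per_px_side=cal.mm_per_px_side,
                    h_mm=h_mm,
                    r_mm=r_mm,
                    lei_deg=lei_deg,
                )
            )
        except (FrameLoadError, geometry.MeasurementError, ValueError) as exc:
            logger.warning("skip (%s, t=%d): %s", plant_id, t, exc)
    return records


def aggregate_group(
    records: Sequence[LEIRecord],
    label: str,
    onset_min: int,
    per_plant_normalize: bool = False,
) -> GroupTimeCourse:
    """Mean +/- SEM LEI trajectory, normalized to zero at treatment onset.

    SEM uses the sample standard deviation (n-1 denominator) over the plants
    present at each time point; a time point with a single plant reports
    SEM 0 and the course carries an ``"n1_sem"`` flag.  By default the *group
    mean* is shifted so mean(onset) = 0; with ``per_plant_normalize`` each
    plant is first shifted by its own onset value (the mean at onset is then
    still exactly 0, but the SEM at onset collapses to 0 too).
    """
    if not records:
        raise NormalizationError("no records to aggregate")
    df = pd.DataFrame(
        {
            "plant_id": [r.plant_id for r in records],
            "timestamp_min": [r.timestamp_min for r in records],
            "lei_deg": [r.lei_deg for r in records],
        }
    )
    if not (df["timestamp_min"] == onset_min).any():
        raise NormalizationError(
            f"group {label!r}: no record at onset t={onset_min} min; "
            "normalization is undefined"
        )
    if per_plant_normalize:
        onset_by_plant = (
            df[df["timestamp_min"] == onset_min].set_index("plant_id")["lei_deg"]
        )
        missing = set(df["plant_id"]) - set(onset_by_plant.index)
        if missing:
            raise NormalizationError(
                f"group {label!r}: plants {sorted(missing)} lack an onset record"
            )
        df["lei_deg"] = df["lei_deg"] - df["plant_id"].map(onset_by_plant)

    grouped = df.groupby("timestamp_min")["lei_deg"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    n = grouped.count()
    sem = (sd / np.sqrt(n)).where(n > 1, 0.0)
    flags: tuple[str, ...] = ("n1_sem",) if (n == 1).any() else ()
    mean_dlei = mean - mean.loc[onset_min]
    return GroupTimeCourse(
        label=label,
        timepoints=[int(t) for t in mean.index],
        mean_dlei=[float(v) for v in mean_dlei],
        sem=[float(v) for v in sem],
        n=[int(v) for v in n],
        flags=flags,
    )


def write_group_csv(courses: Sequence[GroupTimeCourse], path: str | Path) -> Path:
    """Write group trajectories as ``label,timestamp_min,mean_dlei_deg,sem_deg,n``."""
    if not courses:
        raise ValueError("no group time courses to write")
    rows = []
    for course in courses:
        for t, m, s, cnt in zip(course.timepoints, course.mean_dlei, course.sem, course.n):
            rows.append(
                {
                    "label": course.label,
                    "timestamp_min": t,
                    "mean_dlei_deg": m,
                    "sem_deg": s,
                    "n": cnt,
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=list(GROUP_COLUMNS)).to_csv(path, index=False)
    return path
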