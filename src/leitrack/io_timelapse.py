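"""Reading time-lapse image pairs and writing measurement tables.

A time-lapse experiment produces one top-view and one side-view photograph
per plant per time point.  Identity and timing are encoded in the filename
as ``<plantID>_<view>_<minutes>.png`` (or ``.jpg``), e.g. ``p07_top_0600.png``
is the top view of plant ``p07`` taken 600 minutes after the series start.
The convention is ours; an alternative regex with named groups ``plant``,
``view`` and ``t`` may be supplied wherever filenames are parsed.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default filename pattern: ``<plantID>_<view>_<minutes>.<ext>``.
#: The plant ID may itself contain underscores; view and minutes are the
#: last two underscore-separated tokens before the extension.
DEFAULT_FILENAME_PATTERN = re.compile(
    r"^(?P<plant>.+)_(?P<view>[A-Za-z]+)_(?P<t>\d+)\.(?:png|jpg|jpeg)$",
    re.IGNORECASE,
)

#: Column order of the measurement table (CSV and JSON share it).
MEASUREMENT_COLUMNS = (
    "plant_id",
    "timestamp_min",
    "major_px",
    "minor_px",
    "height_px",
    "mm_per_px_top",
    "mm_per_px_side",
    "h_mm",
    "r_mm",
    "lei_deg",
)


class FilenameParseError(ValueError):
    """Filename does not follow the ``<plantID>_<view>_<minutes>`` convention."""


class UnknownViewError(FilenameParseError):
    """The view token is neither ``top`` nor ``side``."""


class DuplicateFrameError(ValueError):
    """Two files claim the same (plant, view, timestamp)."""


class FrameLoadError(OSError):
    """An image file could not be decoded."""


class View(str, enum.Enum):
    TOP = "top"
    SIDE = "side"


@dataclass(frozen=True)
class FrameMeta:
    """Identity of one photograph: which plant, which camera, when."""

    plant_id: str
    view: View
    timestamp_min: int
    path: Path | None = None

    def __post_init__(self) -> None:
        if self.timestamp_min < 0:
            raise ValueError(f"timestamp_min must be >= 0, got {self.timestamp_min}")


@dataclass
class Frame:
    """One decoded photograph: an H x W x 3 uint8 pixel grid plus its metadata."""

    meta: FrameMeta
    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError(f"pixels must be H x W x 3, got shape {p.shape}")
        self.pixels = p.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SeriesIndex:
    """All frames of a time-lapse series grouped into dual-view pairs.

    ``pairs`` maps ``(plant_id, timestamp_min)`` to the frames found for that
    slot.  Entries with both views are *complete*; the rest are reported in
    ``incomplete`` (never silently dropped).  Frames whose timestamp could not
    be snapped to the sampling grid are listed in ``off_grid``.
    """

    interval_min: int
    pairs: dict[tuple[str, int], dict[View, FrameMeta]] = field(default_factory=dict)
    off_grid: list[FrameMeta] = field(default_factory=list)
    unparseable: list[Path] = field(default_factory=list)

    @property
    def plants(self) -> list[str]:
        return sorted({p for p, _ in self.pairs})

    @property
    def timepoints(self) -> list[int]:
        return sorted({t for _, t in self.pairs})

    @property
    def complete(self) -> list[tuple[str, int]]:
        return sorted(k for k, v in self.pairs.items() if len(v) == 2)

    @property
    def incomplete(self) -> list[tuple[str, int, View]]:
        out = []
        for (plant, t), views in sorted(self.pairs.items()):
            for missing in View:
                if missing not in views:
                    out.append((plant, t, missing))
        return out


def parse_frame_filename(
    name: str, pattern: re.Pattern[str] | str = DEFAULT_FILENAME_PATTERN
) -> FrameMeta:
    """Extract (plant, view, minutes) from a filename.

    Raises
    ------
    FilenameParseError
        If the name does not match the pattern.
    UnknownViewError
        If the view token is not ``top`` or ``side`` (case-insensitive).
    """
    if isinstance(pattern, str):
        pattern = re.compile(pattern)
    m = pattern.match(Path(name).name)
    if m is None:
        raise FilenameParseError(
            f"filename {name!r} does not match <plantID>_<view>_<minutes>.<png|jpg>"
        )
    view_token = m.group("view").lower()
    try:
        view = View(view_token)
    except ValueError:
        raise UnknownViewError(
            f"unknown view token {m.group('view')!r} in {name!r}; expected 'top' or 'side'"
        ) from None
    return FrameMeta(
        plant_id=m.group("plant"),
        view=view,
        timestamp_min=int(m.group("t")),
        path=Path(name),
    )


def _snap_timestamp(t: int, interval_min: int, tolerance: float = 0.1) -> int | None:
    """Snap ``t`` to the nearest multiple of ``interval_min``.

    Capture jitter within ``tolerance`` of the interval is absorbed; anything
    further off the grid returns ``None`` (caller flags the frame).
    """
    nearest = int(round(t / interval_min)) * interval_min
    if abs(t - nearest) <= tolerance * interval_min:
        return nearest
    return None


def index_series(
    directory: str | Path,
    interval_min: int = 30,
    pattern: re.Pattern[str] | str = DEFAULT_FILENAME_PATTERN,
) -> SeriesIndex:
    """Scan a directory of images and group them into dual-view pairs.

    Parameters
    ----------
    directory
        Folder holding the PNG/JPEG frames of one experiment.
    interval_min
        Sampling interval of the capture schedule (default 30 minutes).
    pattern
        Filename regex with named groups ``plant``, ``view``, ``t``.
    """
    directory = Path(directory)
    if interval_min <= 0:
        raise ValueError(f"interval_min must be > 0, got {interval_min}")
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")

    index = SeriesIndex(interval_min=interval_min)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    for path in files:
        try:
            meta = parse_frame_filename(path.name, pattern)
        except FilenameParseError:
            logger.warning("skipping unparseable filename: %s", path)
            index.unparseable.append(path)
            continue
        meta = FrameMeta(meta.plant_id, meta.view, meta.timestamp_min, path)
        snapped = _snap_timestamp(meta.timestamp_min, interval_min)
        if snapped is None:
            logger.warning(
                "frame %s is off the %d-min grid (t=%d); flagged",
                path, interval_min, meta.timestamp_min,
            )
            index.off_grid.append(meta)
            continue
        key = (meta.plant_id, snapped)
        slot = index.pairs.setdefault(key, {})
        if meta.view in slot:
            raise DuplicateFrameError(
                f"duplicate ({meta.plant_id}, {meta.view.value}, t={snapped}): "
                f"{slot[meta.view].path} and {path}"
            )
        slot[meta.view] = FrameMeta(meta.plant_id, meta.view, snapped, path)

    if not index.pairs and not index.off_grid:
        raise FileNotFoundError(f"no parseable frames found in {directory}")
    return index


def load_frame(meta: FrameMeta) -> Frame:
    """Decode the image behind ``meta`` into an RGB frame.

    Grayscale sources are promoted to RGB by channel replication; an alpha
    channel, if present, is dropped.
    """
    if meta.path is None or not Path(meta.path).exists():
        raise FrameLoadError(f"no such file: {meta.path}")
    try:
        pixels = iio.imread(meta.path)
    except Exception as exc:  # imageio raises various decoder errors
        raise FrameLoadError(f"cannot decode {meta.path}: {exc}") from exc
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    elif pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    elif pixels.ndim != 3 or pixels.shape[2] != 3:
        raise FrameLoadError(f"unsupported image layout {pixels.shape} in {meta.path}")
    return Frame(meta=meta, pixels=pixels.astype(np.uint8, copy=False))


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({col: getattr(rec, col) for col in MEASUREMENT_COLUMNS})
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def write_measurements(records: Sequence, path: str | Path, format: str = "csv") -> Path:
    """Write per-frame-pair measurements as CSV or JSON.

    Both formats carry the same flat columns (:data:`MEASUREMENT_COLUMNS`)
    and round-trip losslessly through :func:`read_measurements`.
    """
    if not records:
        raise ValueError("records is empty; nothing to write")
    path = Path(path)
    df = _records_to_frame(records)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement table written by :func:`write_measurements`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh), columns=list(MEASUREMENT_COLUMNS))
    else:
        df = pd.read_csv(path)
    return df[list(MEASUREMENT_COLUMNS)]
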