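"""Synthetic dual-view scenes and shade-avoidance time courses.

Every stage of the pipeline is testable without photographs: this module
renders paired top/side images of an idealized cylindrical plant with
*known* geometry, and simulates multi-plant LEI trajectories with a logistic
shade-avoidance rise, an optional transient decay, a circadian-scale
oscillation and per-plant / per-frame noise.

Geometry of a scene (leaf length L, elevation angle theta, top-silhouette
minor/major ratio e):

* top view    — filled ellipse, semi-axes ``L*cos(theta)`` and
  ``e*L*cos(theta)`` (mm), i.e. the projection of leaves of length L
  elevated at angle theta;
* side view   — filled isoceles triangle (leaves rising from the rosette
  edge to a central apex), apex ``L*sin(theta)`` above the soil row; height
  extraction only uses the apex, so the triangle shape does not bias LEI;
* ground truth — ``r_true = L*cos(theta)*(1+e)/2``, ``h_true = L*sin(theta)``
  and ``lei_true = arctan(h_true/r_true)`` in degrees, always evaluated
  through the same formula the pipeline applies.  With ``e = 1``,
  ``lei_true == theta`` identically.

Silhouettes are hard-edged by default so pixel-count oracles are exact;
``antialias=True`` softens edges for robustness testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import filters

from .io_timelapse import Frame, FrameMeta, View

TRUTH_COLUMNS = ("plant_id", "timestamp_min", "lei_true_deg", "r_true_mm", "h_true_mm")


class SceneError(ValueError):
    """The requested silhouette does not fit inside the image."""


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics and noise of one rendered plant scene.

    Defaults describe a young Arabidopsis rosette (leaf length 20 mm) in a
    256x256 frame at 0.2 mm/px — the working distance of a small single-board
    camera 18 cm from the plant.
    """

    leaf_length_mm: float = 20.0
    elevation_deg: float = 30.0
    eccentricity: float = 1.0  # minor/major ratio of the top silhouette
    mm_per_px_top: float = 0.2
    mm_per_px_side: float = 0.2
    top_shape: tuple[int, int] = (256, 256)
    side_shape: tuple[int, int] = (256, 256)
    soil_row: int = 220
    plant_rgb: tuple[int, int, int] = (40, 190, 40)
    background_rgb: tuple[int, int, int] = (26, 22, 16)
    noise_sd: float = 0.0  # Gaussian, on [0, 1] channel scale
    seed: int | None = None
    antialias: bool = False

    def __post_init__(self) -> None:
        if self.leaf_length_mm <= 0:
            raise ValueError("leaf_length_mm must be > 0")
        if not 0 <= self.elevation_deg < 90:
            raise ValueError("elevation_deg must be in [0, 90)")
        if not 0 < self.eccentricity <= 1:
            raise ValueError("eccentricity must be in (0, 1]")
        if not 0 <= self.noise_sd <= 0.2:
            raise ValueError("noise_sd must be in [0, 0.2]")


@dataclass(frozen=True)
class SceneTruth:
    """Exact cylinder geometry of a rendered scene, via the LEI formula."""

    r_true_mm: float
    h_true_mm: float
    lei_true_deg: float
    top_pixels: int
    side_pixels: int


@dataclass(frozen=True)
class ResponseModel:
    """Parametric LEI trajectory of one genotype x treatment condition.

    LEI_i(t) = baseline + b_i + A * sigma(k*(s - t50)) * D(s)
               + osc_amp * sin(2*pi*t / osc_period) + eps_it

    with s = t - onset_min, sigma the logistic function,
    D(s) = exp(-max(0, s - decay_start)/decay_tau) when decay is set else 1,
    b_i ~ N(0, plant_sd^2) a stable between-plant offset and
    eps_it ~ N(0, frame_sd^2) per-frame jitter.  Values are clipped to
    [0, 89] degrees.
    """

    baseline_deg: float = 30.0
    amplitude_deg: float = 25.0
    onset_min: int = 0
    halftime_min: float = 300.0
    rise_rate: float = 0.015  # logistic steepness, 1/min
    osc_amp_deg: float = 2.0
    osc_period_min: float = 1440.0
    decay: tuple[float, float] | None = None  # (start_min, tau_min), after onset
    plant_sd_deg: float = 2.0
    frame_sd_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_deg < 0:
            raise ValueError("amplitude_deg must be >= 0")
        if self.osc_period_min <= 0:
            raise ValueError("osc_period_min must be > 0")
        if self.decay is not None and self.decay[1] <= 0:
            raise ValueError("decay tau must be > 0")

    def evaluate(self, t_min: np.ndarray) -> np.ndarray:
        """Deterministic part of the trajectory (no plant/frame noise)."""
        t = np.asarray(t_min, dtype=np.float64)
        s = t - self.onset_min
        sigma = 1.0 / (1.0 + np.exp(-self.rise_rate * (s - self.halftime_min)))
        if self.decay is not None:
            start, tau = self.decay
            damp = np.exp(-np.maximum(0.0, s - start) / tau)
        else:
            damp = 1.0
        osc = self.osc_amp_deg * np.sin(2.0 * math.pi * t / self.osc_period_min)
        return self.baseline_deg + self.amplitude_deg * sigma * damp + osc


#: Genotype x treatment presets reproducing the qualitative ordering of the
#: published wild-type / pif4 pif5 / pif7 contrasts: numbers are fixtures
#: chosen for that ordering, not measured values.
#:  wt_low       — full shade-avoidance rise, max ~10 h after onset, persists;
#:  wt_high      — no rise (high R:FR control), circadian oscillation only;
#:  pif4pif5_low — slower (max ~15 h) and smaller rise;
#:  pif7_low     — wild-type-like rise rate but transient: decays back to
#:                 baseline by ~20 h of treatment.
PRESETS: dict[str, ResponseModel] = {
    "wt_low": ResponseModel(
        baseline_deg=30.0, amplitude_deg=25.0, halftime_min=300.0, rise_rate=0.015,
        osc_amp_deg=2.0, osc_period_min=1440.0, decay=None,
    ),
    "wt_high": ResponseModel(
        baseline_deg=30.0, amplitude_deg=0.0, halftime_min=300.0, rise_rate=0.015,
        osc_amp_deg=2.0, osc_period_min=1440.0, decay=None,
    ),
    "pif4pif5_low": ResponseModel(
        baseline_deg=30.0, amplitude_deg=12.0, halftime_min=450.0, rise_rate=0.008,
        osc_amp_deg=2.0, osc_period_min=1440.0, decay=None,
    ),
    "pif7_low": ResponseModel(
        baseline_deg=30.0, amplitude_deg=20.0, halftime_min=300.0, rise_rate=0.015,
        osc_amp_deg=2.0, osc_period_min=1440.0, decay=(600.0, 280.0),
    ),
}


def _compose(mask: np.ndarray, params: SceneParams, rng: np.random.Generator | None) -> np.ndarray:
    """Paint a silhouette mask onto the background, with optional blur/noise."""
    plant = np.array(params.plant_rgb, dtype=np.float64) / 255.0
    bg = np.array(params.background_rgb, dtype=np.float64) / 255.0
    coverage = mask.astype(np.float64)
    if params.antialias:
        coverage = filters.gaussian(coverage, sigma=0.7, preserve_range=True)
    img = bg[None, None, :] + coverage[:, :, None] * (plant - bg)[None, None, :]
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _top_silhouette(params: SceneParams) -> np.ndarray:
    H, W = params.top_shape
    theta = math.radians(params.elevation_deg)
    a = params.leaf_length_mm * math.cos(theta) / params.mm_per_px_top
    b = params.eccentricity * a
    r0, c0 = (H - 1) / 2.0, (W - 1) / 2.0
    if a >= min(r0, c0, H - 1 - r0, W - 1 - c0):
        raise SceneError(
            f"top silhouette (semi-axis {a:.1f} px) exceeds {H}x{W} frame"
        )
    rr, cc = np.mgrid[0:H, 0:W]
    # major axis along columns, minor along rows
    return ((cc - c0) / a) ** 2 + ((rr - r0) / b) ** 2 <= 1.0


def _side_silhouette(params: SceneParams) -> np.ndarray:
    H, W = params.side_shape
    theta = math.radians(params.elevation_deg)
    h_px = params.leaf_length_mm * math.sin(theta) / params.mm_per_px_side
    half_base = params.leaf_length_mm * math.cos(theta) / params.mm_per_px_side
    if not 0 <= params.soil_row < H:
        raise SceneError(f"soil_row {params.soil_row} outside {H}-row frame")
    apex_row = params.soil_row - int(round(h_px))
    if apex_row < 0:
        raise SceneError(
            f"side silhouette (apex {h_px:.1f} px above soil row "
            f"{params.soil_row}) exceeds the frame top"
        )
    c0 = (W - 1) / 2.0
    if half_base >= min(c0, W - 1 - c0):
        raise SceneError(f"side silhouette half-base {half_base:.1f} px exceeds frame")
    mask = np.zeros((H, W), dtype=bool)
    base_row = params.soil_row - 1  # nothing of the plant at/below the soil line
    if apex_row > base_row:  # degenerate: elevation 0, silhouette vanishes
        return mask
    rr, cc = np.mgrid[0:H, 0:W]
    span = max(base_row - apex_row, 1)
    frac = (rr - apex_row) / span  # 0 at apex, 1 at base
    inside = (rr >= apex_row) & (rr <= base_row) & (
        np.abs(cc - c0) <= frac * half_base
    )
    mask[inside] = True
    mask[apex_row, int(round(c0))] = True  # apex pixel always present
    return mask


def scene_truth(params: SceneParams, top_pixels: int = 0, side_pixels: int = 0) -> SceneTruth:
    """Closed-form cylinder geometry of a scene, via the LEI formula."""
    theta = math.radians(params.elevation_deg)
    r_true = params.leaf_length_mm * math.cos(theta) * (1 + params.eccentricity) / 2.0
    h_true = params.leaf_length_mm * math.sin(theta)
    lei_true = math.degrees(math.atan(h_true / r_true))
    return SceneTruth(
        r_true_mm=r_true,
        h_true_mm=h_true,
        lei_true_deg=lei_true,
        top_pixels=top_pixels,
        side_pixels=side_pixels,
    )


def render_scene(
    params: SceneParams,
    plant_id: str = "synthetic",
    timestamp_min: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[Frame, Frame, SceneTruth]:
    """Render the paired top/side frames of one plant and report ground truth.

    A silhouette that would exceed its frame raises :class:`SceneError`
    rather than clipping silently.
    """
    top_mask = _top_silhouette(params)
    side_mask = _side_silhouette(params)
    if rng is None and params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
    top = Frame(
        meta=FrameMeta(plant_id, View.TOP, timestamp_min),
        pixels=_compose(top_mask, params, rng),
    )
    side = Frame(
        meta=FrameMeta(plant_id, View.SIDE, timestamp_min),
        pixels=_compose(side_mask, params, rng),
    )
    truth = scene_truth(params, int(top_mask.sum()), int(side_mask.sum()))
    return top, side, truth


def simulate_timecourse(
    model: ResponseModel,
    n_plants: int,
    duration_min: int,
    interval_min: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-plant LEI truth trajectories sampled on the capture grid.

    Returns a tidy frame with columns ``plant_id``, ``timestamp_min`` and
    ``lei_deg`` covering t = 0 .. duration_min inclusive.  Identical seeds
    give identical output.
    """
    if duration_min // interval_min + 1 < 2:
        raise ValueError("duration/interval must yield at least 2 timepoints")
    t = np.arange(0, duration_min + 1, interval_min, dtype=np.int64)
    rng = np.random.default_rng(seed)
    base = model.evaluate(t)
    rows = []
    width = max(2, len(str(n_plants)))
    for i in range(n_plants):
        b_i = rng.normal(0.0, model.plant_sd_deg) if model.plant_sd_deg > 0 else 0.0
        eps = (
            rng.normal(0.0, model.frame_sd_deg, size=t.shape)
            if model.frame_sd_deg > 0
            else np.zeros_like(base)
        )
        lei = np.clip(base + b_i + eps, 0.0, 89.0)
        plant_id = f"p{i + 1:0{width}d}"
        for tt, v in zip(t, lei):
            rows.append((plant_id, int(tt), float(v)))
    return pd.DataFrame(rows, columns=["plant_id", "timestamp_min", "lei_deg"])


def _theta_for_lei(lei_deg: float, eccentricity: float) -> float:
    """Elevation angle whose scene truth LEI equals ``lei_deg``.

    Inverts lei = arctan(tan(theta) * 2/(1+e)); with e = 1, theta = lei.
    """
    return math.degrees(
        math.atan(math.tan(math.radians(lei_deg)) * (1 + eccentricity) / 2.0)
    )


def generate_dataset(
    model: ResponseModel,
    scene_base: SceneParams,
    n_plants: int,
    duration_min: int,
    interval_min: int,
    seed: int | None,
    out_dir: str | Path,
) -> Path:
    """Write a full synthetic experiment: image pairs plus a truth table.

    For each plant/time point the scene elevation angle is set so the scene's
    true LEI equals the simulated trajectory value.  Filenames follow the
    ``<plantID>_<view>_<minutes>.png`` convention; ``truth.csv`` lists
    ``plant_id,timestamp_min,lei_true_deg,r_true_mm,h_true_mm`` per pair.
    Re-running with the same seed reproduces the truth table byte for byte.

    Returns the path of ``truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj = simulate_timecourse(model, n_plants, duration_min, interval_min, seed)
    noise_rng = np.random.default_rng(
        None if seed is None else (int(seed) + 783_245) % (2**31)
    )
    lines = [",".join(TRUTH_COLUMNS)]
    for row in traj.itertuples(index=False):
        theta = _theta_for_lei(row.lei_deg, scene_base.eccentricity)
        params = replace(scene_base, elevation_deg=theta)
        top, side, truth = render_scene(
            params, plant_id=row.plant_id, timestamp_min=row.timestamp_min, rng=noise_rng
        )
        for frame in (top, side):
            name = f"{row.plant_id}_{frame.meta.view.value}_{row.timestamp_min:04d}.png"
            iio.imwrite(out_dir / name, frame.pixels)
        lines.append(
            f"{row.plant_id},{row.timestamp_min},"
            f"{truth.lei_true_deg:.9f},{truth.r_true_mm:.9f},{truth.h_true_mm:.9f}"
        )
    truth_path = out_dir / "truth.csv"
    truth_path.write_text("\n".join(lines) + "\n")
    return truth_path
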