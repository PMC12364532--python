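"""Shared fixtures: analytic shape masks and tiny synthetic datasets."""

from __future__ import annotations

import math

import numpy as np
import pytest

from leitrack import BinaryMask


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    phi_deg: float = 0.0,
) -> BinaryMask:
    """Filled ellipse with semi-axes (a, b) px, major axis at phi_deg.

    The angle is measured from the column axis, counter-clockwise with y up
    (rows negated) — the same convention fit_ellipse reports.
    """
    H, W = shape
    r0, c0 = center
    phi = math.radians(phi_deg)
    rr, cc = np.mgrid[0:H, 0:W]
    dx = cc - c0
    dy = -(rr - r0)  # y-up
    x = dx * math.cos(phi) + dy * math.sin(phi)
    y = -dx * math.sin(phi) + dy * math.cos(phi)
    return BinaryMask((x / a) ** 2 + (y / b) ** 2 <= 1.0)


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> BinaryMask:
    return ellipse_mask(shape, center, radius, radius)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
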