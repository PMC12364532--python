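"""LEI formula, calibration, batch measurement and group aggregation."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leitrack import (
    Calibration,
    LEIRecord,
    SceneParams,
    SegmentationParams,
    aggregate_group,
    build_records,
    calibrate,
    compute_lei,
    generate_dataset,
    index_series,
    radius_from_axes,
)
from leitrack.lei_analysis import CalibrationError, NormalizationError
from leitrack.synthetic_data import PRESETS


class TestScalarOperations:
    @pytest.mark.parametrize("px, mm, expected", [(100, 10, 0.1), (1, 1, 1.0), (250, 50, 0.2)])
    def test_calibrate(self, px, mm, expected):
        assert calibrate(px, mm) == pytest.approx(expected)

    @pytest.mark.parametrize("px, mm", [(0, 10), (100, 0), (-5, 10)])
    def test_calibrate_rejects_nonpositive(self, px, mm):
        with pytest.raises(CalibrationError):
            calibrate(px, mm)

    @pytest.mark.parametrize("major, minor, expected", [(20, 20, 10), (24, 16, 10), (30, 0, 7.5)])
    def test_radius_from_axes(self, major, minor, expected):
        assert radius_from_axes(major, minor) == pytest.approx(expected)

    def test_radius_rejects_degenerate(self):
        with pytest.raises(ValueError):
            radius_from_axes(0, 0)

    @pytest.mark.parametrize(
        "h, r, expected",
        [(5, 5, 45.0), (0, 7.3, 0.0), (5 * math.sqrt(3), 5, 60.0)],
    )
    def test_compute_lei_closed_forms(self, h, r, expected):
        assert compute_lei(h, r) == pytest.approx(expected, abs=1e-6)

    def test_compute_lei_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            compute_lei(5, 0)
        with pytest.raises(ValueError):
            compute_lei(-1, 5)

    @settings(derandomize=True, max_examples=100)
    @given(
        h=st.floats(0.01, 100, allow_nan=False),
        r=st.floats(0.01, 100, allow_nan=False),
    )
    def test_complementarity(self, h, r):
        assert compute_lei(h, r) + compute_lei(r, h) == pytest.approx(90.0, abs=1e-9)

    def test_monotone_in_height_and_radius(self):
        assert compute_lei(6, 5) > compute_lei(5, 5) > compute_lei(4, 5)
        assert compute_lei(5, 4) > compute_lei(5, 5) > compute_lei(5, 6)


def _rec(plant, t, lei):
    return LEIRecord(
        plant_id=plant, timestamp_min=t, major_px=100.0, minor_px=80.0,
        height_px=50.0, mm_per_px_top=0.2, mm_per_px_side=0.2,
        h_mm=10.0, r_mm=9.0, lei_deg=lei,
    )


class TestAggregateGroup:
    def test_mean_and_sem_of_three_plants(self):
        records = [_rec(f"p{i}", 0, v) for i, v in enumerate([1.0, 2.0, 3.0])]
        course = aggregate_group(records, "g", onset_min=0)
        assert course.mean_dlei == [0.0]  # normalized at onset
        assert course.sem[0] == pytest.approx(1 / math.sqrt(3), abs=1e-9)
        assert course.n == [3]

    def test_constant_series_gives_zero_dlei(self):
        records = [_rec("p1", t, 25.0) for t in (0, 30, 60)]
        records += [_rec("p2", t, 31.0) for t in (0, 30, 60)]
        course = aggregate_group(records, "g", onset_min=0)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in course.mean_dlei)

    def test_onset_normalization_exact_zero(self):
        rng = np.random.default_rng(7)
        records = [
            _rec(f"p{i}", t, float(rng.uniform(10, 60)))
            for i in range(4)
            for t in (0, 30, 60, 90)
        ]
        course = aggregate_group(records, "g", onset_min=0)
        assert course.mean_dlei[course.timepoints.index(0)] == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(11)
        base = [
            _rec(f"p{i}", t, float(rng.uniform(10, 60)))
            for i in range(3)
            for t in (0, 30, 60)
        ]
        shifted = [replace(r, lei_deg=r.lei_deg + 7.5) for r in base]
        a = aggregate_group(base, "g", 0)
        b = aggregate_group(shifted, "g", 0)
        np.testing.assert_allclose(a.mean_dlei, b.mean_dlei, atol=1e-12)

    def test_single_plant_sem_zero_with_flag(self):
        course = aggregate_group([_rec("p1", 0, 20.0), _rec("p1", 30, 25.0)], "g", 0)
        assert course.sem == [0.0, 0.0]
        assert "n1_sem" in course.flags

    def test_unequal_n_reported_per_timepoint(self):
        records = [_rec("p1", 0, 20.0), _rec("p2", 0, 22.0), _rec("p1", 30, 25.0)]
        course = aggregate_group(records, "g", 0)
        assert course.n == [2, 1]

    def test_missing_onset_errors(self):
        with pytest.raises(NormalizationError):
            aggregate_group([_rec("p1", 30, 20.0)], "g", onset_min=0)

    def test_per_plant_normalization_also_zeroes_onset(self):
        records = [_rec("p1", 0, 20.0), _rec("p1", 30, 30.0),
                   _rec("p2", 0, 40.0), _rec("p2", 30, 44.0)]
        course = aggregate_group(records, "g", 0, per_plant_normalize=True)
        assert course.mean_dlei[0] == 0.0
        assert course.mean_dlei[1] == pytest.approx(7.0)  # mean of +10 and +4


@pytest.fixture(scope="module")
def noiseless_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    model = replace(
        PRESETS["wt_low"], plant_sd_deg=0.0, frame_sd_deg=0.0, osc_amp_deg=0.0
    )
    truth_path = generate_dataset(
        model, SceneParams(), n_plants=1, duration_min=120, interval_min=60,
        seed=5, out_dir=out,
    )
    return out, truth_path


class TestBuildRecords:
    def test_recovers_truth_within_two_degrees(self, noiseless_dataset):
        out, truth_path = noiseless_dataset
        import pandas as pd

        truth = pd.read_csv(truth_path)
        series = index_series(out, interval_min=60)
        records = build_records(
            series, SegmentationParams(), line_position=220,
            cal=Calibration(0.2, 0.2),
        )
        assert len(records) == 3
        for rec in records:
            expect = truth.loc[
                (truth.plant_id == rec.plant_id)
                & (truth.timestamp_min == rec.timestamp_min),
                "lei_true_deg",
            ].item()
            assert abs(rec.lei_deg - expect) <= 2.0

    def test_black_side_frame_becomes_logged_skip(self, noiseless_dataset, tmp_path, caplog):
        import shutil
        import imageio.v3 as iio

        out, _ = noiseless_dataset
        work = tmp_path / "work"
        shutil.copytree(out, work)
        side = work / "p01_side_0060.png"
        iio.imwrite(side, np.zeros((256, 256, 3), np.uint8))
        series = index_series(work, interval_min=60)
        with caplog.at_level("WARNING", logger="leitrack.lei_analysis"):
            records = build_records(
                series, SegmentationParams(), 220, Calibration(0.2, 0.2)
            )
        assert len(records) == 2
        assert any("skip" in r.message for r in caplog.records)

    def test_empty_series_warns_and_returns_empty(self, tmp_path, caplog):
        import imageio.v3 as iio
        from leitrack.io_timelapse import index_series as idx

        iio.imwrite(tmp_path / "p1_top_0000.png", np.zeros((8, 8, 3), np.uint8))
        series = idx(tmp_path, interval_min=30)
        with caplog.at_level("WARNING", logger="leitrack.lei_analysis"):
            records = build_records(
                series, SegmentationParams(), 4, Calibration(0.2, 0.2)
            )
        assert records == []
        assert any("no complete" in r.message for r in caplog.records)
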