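"""Thickness-index computation: threshold formula, counting, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glycovivo import (
    GeometryError,
    ImageFrame,
    OrientedROI,
    SceneSpec,
    ThresholdParams,
    binarize_and_count,
    compute_threshold,
    compute_ti,
    extract_roi,
    render_vessel_scene,
    roi_on_wall,
    summarize_vessels,
)

import pandas as pd


patches = hnp.arrays(np.uint8, (12, 17), elements=st.integers(0, 255))


class TestThreshold:
    @pytest.mark.parametrize(
        "imax,imin,F,expected",
        [(255, 0, 0.7, 178.5), (255, 0, 1.0, 255.0), (255, 0, 0.0, 0.0),
         (37, 37, 0.7, 37.0), (200, 100, 0.5, 150.0)],
    )
    def test_formula_cases(self, imax, imin, F, expected):
        patch = np.array([[imin, imax]], dtype=np.uint8)
        assert compute_threshold(patch, ThresholdParams(F=F)) == expected

    def test_against_bruteforce_minmax(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            patch = rng.integers(0, 256, (15, 23), dtype=np.uint8)
            # oracle: pure-python scan for the extremes
            flat = [int(v) for row in patch for v in row]
            expected = 0.7 * (max(flat) - min(flat)) + min(flat)
            assert compute_threshold(patch) == pytest.approx(expected, abs=1e-12)

    def test_rounding_option(self):
        patch = np.array([[0, 255]], dtype=np.uint8)
        assert compute_threshold(patch, ThresholdParams(round_threshold=True)) == 178

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(np.empty((0, 0), dtype=np.uint8))

    def test_invalid_F_rejected(self):
        with pytest.raises(ValueError):
            ThresholdParams(F=1.2)


class TestBinarizeAndCount:
    def test_uniform_band_exact_count(self):
        patch = np.zeros((40, 200), dtype=np.uint8)
        patch[10:15] = 255  # 5 rows at full brightness
        th = compute_threshold(patch)  # 178.5
        assert binarize_and_count(patch, th) == 5 * 200

    def test_all_equal_counts_everything(self):
        patch = np.full((40, 200), 123, dtype=np.uint8)
        assert binarize_and_count(patch, 123.0) == 8000

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            patch = rng.integers(0, 256, (10, 20), dtype=np.uint8)
            th = compute_threshold(patch)
            expected = sum(
                1 for i in range(10) for j in range(20) if patch[i, j] >= th)
            assert binarize_and_count(patch, th) == expected

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(patch=patches, f1=st.floats(0, 1), f2=st.floats(0, 1))
    def test_count_nonincreasing_in_F(self, patch, f1, f2):
        """Raising F raises Th and can only shrink the counted class."""
        lo, hi = sorted([f1, f2])
        c_lo = binarize_and_count(patch, compute_threshold(patch, ThresholdParams(F=lo)))
        c_hi = binarize_and_count(patch, compute_threshold(patch, ThresholdParams(F=hi)))
        assert c_hi <= c_lo


class TestExtractROI:
    def test_identity_at_angle_zero(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (40, 200), dtype=np.uint8)
        frame = ImageFrame(img)
        patch = extract_roi(frame, OrientedROI(anchor=(0, 0)))
        assert np.array_equal(patch, img)

    def test_angle_ninety_is_transposed_subimage(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (210, 60), dtype=np.uint8)
        frame = ImageFrame(img)
        patch = extract_roi(frame, OrientedROI(anchor=(0, 45),
                                               long_axis_angle=90.0))
        # width direction at 90 degrees runs toward smaller columns
        expected = img[0:200, 6:46][:, ::-1].T
        assert np.array_equal(patch, expected)

    def test_out_of_bounds_raises(self):
        frame = ImageFrame(np.zeros((50, 50), dtype=np.uint8))
        with pytest.raises(GeometryError):
            extract_roi(frame, OrientedROI(anchor=(0, 0)))

    def test_rotated_extraction_matches_ground_truth_band(self):
        """Wall ROI on a rotated scene recovers band rows within 1 px."""
        spec = SceneSpec(vessel_axis_angle=25.0, noise_sd=0,
                         image_shape=(301, 301))
        frame, gt = render_vessel_scene(spec)
        patch = extract_roi(frame, roi_on_wall(gt))
        band_rows = (patch == spec.band_intensity).sum(axis=0)
        assert np.abs(band_rows - 5).max() <= 1


class TestComputeTI:
    @pytest.mark.parametrize("thickness_px", [1, 2, 3, 5, 10, 20])
    def test_noise_free_recovery(self, thickness_px):
        spec = SceneSpec(gcx_thickness_true=thickness_px * 0.377, noise_sd=0)
        frame, gt = render_vessel_scene(spec)
        res = compute_ti(frame, roi_on_wall(gt))
        assert abs(res.ti_px - thickness_px) <= 1.0
        assert res.ti_um == pytest.approx(res.ti_px * 0.377)

    def test_five_px_band_gives_1885_nm(self):
        frame, gt = render_vessel_scene(SceneSpec(noise_sd=0))
        res = compute_ti(frame, roi_on_wall(gt))
        assert res.ti_px == 5.0
        assert res.ti_um == pytest.approx(1.885)

    def test_zero_thickness_near_zero_ti(self):
        """No band: an interstitial ROI shows only noise exceedances.

        (An ROI straddling the lumen would count the lumen as the bright
        class instead; the thickness index presumes a visible band.)
        """
        frame, gt = render_vessel_scene(
            SceneSpec(gcx_thickness_true=0.0, noise_sd=5.0, seed=1))
        roi = roi_on_wall(gt)
        # shift the ROI fully onto the background side of the wall
        shifted = OrientedROI(
            anchor=(roi.anchor[0] + 25, roi.anchor[1]),
            long_axis_angle=roi.long_axis_angle)
        res = compute_ti(frame, shifted)
        assert res.ti_px < 1.0

    def test_flat_patch_flagged_degenerate(self):
        frame = ImageFrame(np.full((60, 220), 37, dtype=np.uint8))
        res = compute_ti(frame, OrientedROI(anchor=(5, 5)))
        assert res.degenerate
        assert np.isnan(res.ti_px) and np.isnan(res.ti_um)

    def test_monotone_in_true_thickness_under_noise(self):
        tis = []
        for um in (0.5, 1.0, 1.5, 2.0, 3.0):
            frame, gt = render_vessel_scene(
                SceneSpec(gcx_thickness_true=um, noise_sd=5.0, seed=8))
            tis.append(compute_ti(frame, roi_on_wall(gt)).ti_um)
        assert all(b >= a for a, b in zip(tis, tis[1:]))

    def test_pixel_size_covariance(self):
        """Doubling pixel size doubles ti_um and leaves ti_px unchanged."""
        spec = SceneSpec(noise_sd=0)
        frame, gt = render_vessel_scene(spec)
        res1 = compute_ti(frame, roi_on_wall(gt))
        frame2 = ImageFrame(frame.pixels, pixel_size=2 * spec.pixel_size)
        res2 = compute_ti(frame2, roi_on_wall(gt))
        assert res2.ti_px == res1.ti_px
        assert res2.ti_um == pytest.approx(2 * res1.ti_um)


class TestSummarize:
    def test_identical_values(self):
        df = pd.DataFrame({"vessel_class": "arteriole", "hour": 0,
                           "ti_um": [1.5] * 21})
        out = summarize_vessels(df)
        assert out.loc[0, "mean"] == 1.5
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "n"] == 21

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.normal(1.3, 0.3, 21)
        df = pd.DataFrame({"vessel_class": "venule", "hour": 24,
                           "ti_um": values})
        out = summarize_vessels(df)
        mean = sum(values) / len(values)
        sd = (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
        assert out.loc[0, "mean"] == pytest.approx(mean, rel=1e-12)
        assert out.loc[0, "sd"] == pytest.approx(sd, rel=1e-12)

    def test_single_measurement_group_rejected(self):
        df = pd.DataFrame({"vessel_class": ["a"], "hour": [0], "ti_um": [1.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            summarize_vessels(df)
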