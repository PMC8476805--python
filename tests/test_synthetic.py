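"""Generator contracts: ground truth, determinism, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from glycovivo import (
    CohortSpec,
    LeakSpec,
    SceneSpec,
    TrackSpec,
    permeability_index,
    render_vessel_scene,
    simulate_cohort,
    simulate_leak_series,
    simulate_tracks,
)


class TestVesselScene:
    @pytest.mark.parametrize("thickness_px", [1, 2, 5, 10, 20])
    def test_band_mask_exact_thickness(self, thickness_px):
        """An axis-aligned band of n*pixel_size um is exactly n px thick."""
        spec = SceneSpec(gcx_thickness_true=thickness_px * 0.377, noise_sd=0)
        _, gt = render_vessel_scene(spec)
        per_column = gt.band_mask.sum(axis=0)
        # two walls, each exactly thickness_px rows
        assert np.all(per_column == 2 * thickness_px)

    def test_intensities_noise_free(self):
        frame, gt = render_vessel_scene(SceneSpec(noise_sd=0))
        assert np.all(frame.pixels[gt.band_mask] == 200)
        assert set(np.unique(frame.pixels)) == {10, 80, 200}

    def test_determinism(self):
        spec = SceneSpec(noise_sd=8.0, seed=42)
        f1, g1 = render_vessel_scene(spec)
        f2, g2 = render_vessel_scene(spec)
        assert np.array_equal(f1.pixels, f2.pixels)
        assert np.array_equal(g1.band_mask, g2.band_mask)

    def test_zero_thickness_empty_mask(self):
        frame, gt = render_vessel_scene(SceneSpec(gcx_thickness_true=0.0,
                                                  noise_sd=0))
        assert gt.band_mask.sum() == 0
        assert set(np.unique(frame.pixels)) == {10, 80}

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="too small"):
            render_vessel_scene(SceneSpec(image_shape=(40, 40)))

    def test_diameter_outside_selection_range_warns(self):
        with pytest.warns(UserWarning, match="diameter"):
            SceneSpec(vessel_diameter=60.0)

    def test_band_must_be_bright(self):
        with pytest.raises(ValueError):
            SceneSpec(band_intensity=70, lumen_intensity=80)

    def test_rotated_scene_mask_consistent_with_truth(self):
        """Mask pixel count / axis length * pixel size ~ 2 walls x thickness."""
        spec = SceneSpec(vessel_axis_angle=30.0, gcx_thickness_true=1.885,
                         noise_sd=0, image_shape=(301, 301))
        _, gt = render_vessel_scene(spec)
        # axis length in px across the image along the 30-degree direction
        h, w = spec.image_shape
        axis_len = min(w / np.cos(np.radians(30)), h / np.sin(np.radians(30)))
        mean_thickness_px = gt.band_mask.sum() / axis_len
        assert mean_thickness_px == pytest.approx(2 * 5.0, abs=1.0)


class TestTracks:
    def test_sample_count(self):
        tracks, _ = simulate_tracks(TrackSpec(frame_rate=2.0, window=15.0))
        assert all(len(t.t_s) == 31 for t in tracks)
        assert all(t.t_s[0] == 0.0 and t.t_s[-1] == 15.0 for t in tracks)

    def test_adhering_displacement_bound(self):
        spec = TrackSpec(n_adhering=3, n_rolling=0, n_flowing=0,
                         jitter_sd=0.5, seed=7)
        tracks, labels = simulate_tracks(spec)
        assert labels == ["adhering"] * 3
        for t in tracks:
            disp = np.hypot(t.x_um - t.x_um[0], t.y_um - t.y_um[0])
            assert disp.max() <= 3 * spec.jitter_sd + 1e-12

    def test_rolling_speed_recovered_from_coordinates(self):
        spec = TrackSpec(n_adhering=0, n_rolling=10, n_flowing=0,
                         rolling_speed_fraction=0.2, centerline_speed=100.0,
                         jitter_sd=0.0, seed=1)
        tracks, _ = simulate_tracks(spec)
        for t in tracks:
            speed = np.hypot(t.x_um[-1] - t.x_um[0],
                             t.y_um[-1] - t.y_um[0]) / (t.t_s[-1] - t.t_s[0])
            assert speed == pytest.approx(20.0, rel=1e-9)

    def test_lateral_confinement(self):
        spec = TrackSpec(seed=5, jitter_sd=0.0, axis_angle_deg=0.0)
        tracks, _ = simulate_tracks(spec)
        for t in tracks:
            assert np.all(np.abs(t.y_um) <= spec.vessel_diameter / 2)

    def test_class_speed_separation(self):
        """The three classes have non-overlapping net-speed distributions."""
        tracks, labels = simulate_tracks(TrackSpec(seed=11, jitter_sd=0.5))
        speeds = {lab: [] for lab in ("adhering", "rolling", "flowing")}
        for t, lab in zip(tracks, labels):
            speeds[lab].append(
                np.hypot(t.x_um[-1] - t.x_um[0], t.y_um[-1] - t.y_um[0]) / 15.0)
        assert max(speeds["adhering"]) < min(speeds["rolling"])
        assert max(speeds["rolling"]) < min(speeds["flowing"])

    def test_determinism(self):
        a, _ = simulate_tracks(TrackSpec(seed=3, jitter_sd=1.0))
        b, _ = simulate_tracks(TrackSpec(seed=3, jitter_sd=1.0))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x_um, tb.x_um)
            assert np.array_equal(ta.y_um, tb.y_um)


class TestLeakSeries:
    def test_zero_rate_noise_free_constant(self):
        series, _ = simulate_leak_series(LeakSpec(leak_rate=0.0, noise_sd=0.0))
        idx = permeability_index(series)
        assert np.all(idx["index"] == 0.0)

    def test_linear_rise_noise_free(self):
        series, _ = simulate_leak_series(LeakSpec(leak_rate=0.5, noise_sd=0.0))
        idx = permeability_index(series)
        agg = idx[idx.roi_id == -1].sort_values("t_min")
        assert agg["index"].tolist() == [0.0, 15.0, 30.0, 45.0, 60.0]

    def test_ensemble_slope_recovers_rate(self):
        """Regression over a 100-seed ensemble recovers the leak rate."""
        rate = 0.4
        times = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        means = np.zeros_like(times)
        for seed in range(100):
            series, _ = simulate_leak_series(
                LeakSpec(leak_rate=rate, noise_sd=5.0, seed=seed))
            idx = permeability_index(series)
            agg = idx[idx.roi_id == -1].sort_values("t_min")
            means += agg["index"].to_numpy()
        means /= 100
        slope = np.polyfit(times, means, 1)[0]
        assert slope == pytest.approx(rate, rel=0.05)

    def test_times_must_include_zero(self):
        with pytest.raises(ValueError):
            LeakSpec(times=(30.0, 60.0))


class TestCohort:
    def _spec(self, **kw):
        base = dict(variable="sdc1", schedule=(0, 24),
                    group_means={0: 1.85, 24: 3.83},
                    group_sds={0: 0.48, 24: 1.09}, n_per_time=3, seed=0)
        base.update(kw)
        return CohortSpec(**base)

    def test_zero_sd_gives_exact_means(self):
        table = simulate_cohort(self._spec(group_sds={0: 0.0, 24: 0.0}))
        by_hour = table.data.groupby("hour")["value"].unique()
        assert list(by_hour[0]) == [1.85]
        assert list(by_hour[24]) == [3.83]

    def test_large_n_recovers_printed_mean(self):
        table = simulate_cohort(self._spec(n_per_time=10_000, seed=2))
        m24 = table.data.query("hour == 24")["value"].mean()
        assert m24 == pytest.approx(3.83, abs=0.05)

    def test_truncation_at_zero(self):
        table = simulate_cohort(self._spec(
            group_means={0: 0.3, 24: 0.3}, group_sds={0: 1.0, 24: 1.0},
            n_per_time=500, seed=4))
        assert (table.data["value"] >= 0).all()

    def test_determinism(self):
        t1 = simulate_cohort(self._spec(seed=9))
        t2 = simulate_cohort(self._spec(seed=9))
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_missing_hour_parameters_raise(self):
        with pytest.raises(ValueError, match="missing mean or SD"):
            self._spec(schedule=(0, 24, 48))

    def test_off_grid_hour_rejected(self):
        with pytest.raises(ValueError, match="protocol grid"):
            self._spec(schedule=(0, 12))

    def test_n_per_time_minimum(self):
        with pytest.raises(ValueError, match="n_per_time"):
            self._spec(n_per_time=1)
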