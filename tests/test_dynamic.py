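"""Dynamic-contrast pipeline: STD, spectra, band integration, rendering."""

import numpy as np
import pytest

from dffocm import (
    BandDefinition,
    RenderConfig,
    assemble_volume,
    dynamic_pipeline,
    integrate_bands,
    mean_spectrum,
    pixel_spectrum,
    render_rgb,
    simulate_stack,
    temporal_std,
)
from dffocm.errors import DegenerateInputError, ParameterError
from dffocm.fixtures import static_sample_spec, three_band_spec

from conftest import make_stack


class TestTemporalStd:
    def test_constant_series_is_zero(self):
        assert temporal_std(make_stack(np.ones((16, 3, 3)))).max() == 0.0

    def test_alternating_series_closed_form(self):
        # values a, -a around mean m: sample SD = a * sqrt(T / (T - 1))
        a, m, t = 2.0, 5.0, 32
        frames = np.full((t, 2, 2), m)
        frames[::2] += a
        frames[1::2] -= a
        expected = a * np.sqrt(t / (t - 1))
        np.testing.assert_allclose(temporal_std(make_stack(frames)), expected,
                                   rtol=1e-12)

    def test_sinusoid_rms(self):
        # integer periods at 500 fps, T=500: SD -> a/sqrt(2) up to the T-1 factor
        a, t = 3.0, 500
        series = a * np.sin(2 * np.pi * 10 * np.arange(t) / 500.0) + 10.0
        frames = np.broadcast_to(series[:, None, None], (t, 2, 2))
        sd = temporal_std(make_stack(frames))
        np.testing.assert_allclose(sd, a / np.sqrt(2), rtol=0.01)

    def test_invariant_to_per_pixel_temporal_constant(self, noise_stack, rng):
        offset = rng.random((6, 6)) * 50
        shifted = make_stack(noise_stack.frames + offset[None])
        np.testing.assert_allclose(temporal_std(shifted),
                                   temporal_std(noise_stack), rtol=1e-9)

    def test_single_frame_cannot_form_a_stack(self):
        with pytest.raises(ParameterError):
            make_stack(np.ones((1, 2, 2)))


class TestPixelSpectrum:
    def test_constant_series_all_ac_bins_zero(self):
        cube = pixel_spectrum(make_stack(np.full((32, 3, 3), 4.0)))
        assert np.abs(cube.magnitudes[1:]).max() < 1e-14

    def test_pure_tone_power_in_one_bin(self):
        t, k = 128, 10
        series = 1.0 * np.cos(2 * np.pi * k * np.arange(t) / t) + 2.0
        frames = np.broadcast_to(series[:, None, None], (t, 2, 2))
        cube = pixel_spectrum(make_stack(frames))
        power = cube.power[:, 0, 0]
        assert power[k] / power[1:].sum() > 1 - 1e-10
        # unit cosine has variance 1/2; the one-sided bin carries all of it
        assert power[k] == pytest.approx(0.5, rel=1e-10)

    def test_parseval_ac_power_equals_variance(self, noise_stack):
        cube = pixel_spectrum(noise_stack)
        var = noise_stack.frames.var(axis=0)  # population variance
        ac = cube.power[1:].sum(axis=0)
        np.testing.assert_allclose(ac, var, rtol=1e-10)

    def test_parseval_holds_for_odd_frame_count(self, rng):
        stack = make_stack(rng.random((63, 4, 4)) + 1)
        cube = pixel_spectrum(stack)
        np.testing.assert_allclose(cube.power[1:].sum(axis=0),
                                   stack.frames.var(axis=0), rtol=1e-10)

    def test_tiled_processing_matches_untiled(self, noise_stack):
        full = pixel_spectrum(noise_stack)
        tiled = pixel_spectrum(noise_stack, tile_rows=2)
        np.testing.assert_array_equal(full.magnitudes, tiled.magnitudes)

    def test_bin_spacing_is_frame_rate_over_n(self, noise_stack):
        cube = pixel_spectrum(noise_stack)
        np.testing.assert_allclose(np.diff(cube.freqs), 500.0 / 128)


class TestIntegrateBands:
    def test_zero_spectrum_gives_zero_maps(self):
        cube = pixel_spectrum(make_stack(np.full((64, 3, 3), 2.0)))
        maps = integrate_bands(cube, BandDefinition())
        np.testing.assert_array_equal(maps, 0.0)

    def test_tone_at_150hz_lands_in_high_band_only(self):
        t = 500
        series = np.cos(2 * np.pi * 150 * np.arange(t) / 500.0) + 2.0
        frames = np.broadcast_to(series[:, None, None], (t, 2, 2))
        cube = pixel_spectrum(make_stack(frames))
        low, mid, high = integrate_bands(cube, BandDefinition(), "power")
        assert high[0, 0] > 0.49
        assert low.max() < 1e-20 and mid.max() < 1e-20

    def test_partition_conservation_over_full_axis(self, noise_stack):
        # bands tiling (0, Nyquist] in power mode must reproduce the variance
        bands = BandDefinition((1e-6, 50.0), (50.0, 150.0), (150.0, 250.0))
        maps = integrate_bands(pixel_spectrum(noise_stack), bands, "power")
        np.testing.assert_allclose(maps.sum(axis=0),
                                   noise_stack.frames.var(axis=0), rtol=1e-10)

    def test_shared_edge_goes_to_upper_band(self):
        t = 500  # 1 Hz bins; a tone exactly at a shared edge
        series = np.cos(2 * np.pi * 100 * np.arange(t) / 500.0) + 2.0
        frames = np.broadcast_to(series[:, None, None], (t, 1, 1))
        cube = pixel_spectrum(make_stack(frames))
        low, mid, high = integrate_bands(cube, BandDefinition(), "power")
        assert mid[0, 0] < 1e-20
        assert high[0, 0] > 0.49

    def test_empty_band_warns_and_zeroes(self, noise_stack):
        bands = BandDefinition((0.1, 0.5), (0.5, 100.0), (100.0, 250.0))
        with pytest.warns(UserWarning, match="no spectral bins"):
            maps = integrate_bands(pixel_spectrum(noise_stack), bands)
        np.testing.assert_array_equal(maps[0], 0.0)

    def test_band_edges_beyond_nyquist_rejected(self, noise_stack):
        cube = pixel_spectrum(noise_stack)
        with pytest.raises(ParameterError):
            integrate_bands(cube, BandDefinition((1, 3), (3, 100), (100, 400)))


class TestRenderRgb:
    def test_distinct_values_saturate_exactly_one_percent(self):
        values = np.arange(200 * 200, dtype=float).reshape(200, 200) + 1.0
        rgb = render_rgb(np.stack([values] * 3))
        for chan in rgb:
            assert (chan == 1.0).mean() == pytest.approx(0.01)
            assert (chan == 0.0).mean() == pytest.approx(0.01)

    def test_all_zero_map_renders_zero(self):
        with pytest.warns(UserWarning, match="constant channel"):
            rgb = render_rgb(np.zeros((3, 10, 10)))
        np.testing.assert_array_equal(rgb, 0.0)

    def test_scale_invariance_well_above_epsilon(self, rng):
        maps = np.stack([rng.random((50, 50)) + 1.0] * 3)
        a = render_rgb(maps, RenderConfig(log_epsilon=1e-30))
        b = render_rgb(maps * 10, RenderConfig(log_epsilon=1e-30))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_output_channel_order_is_rgb(self, rng):
        maps = np.zeros((3, 20, 20))
        maps[0] = rng.random((20, 20))  # low band -> blue channel
        with pytest.warns(UserWarning, match="constant channel"):
            rgb = render_rgb(maps)
        assert rgb[2].max() > 0  # blue populated
        assert rgb[0].max() == 0 and rgb[1].max() == 0


class TestPipeline:
    def test_three_regions_get_blue_green_red_hues(self):
        spec = three_band_spec(seed=0)
        img = dynamic_pipeline(simulate_stack(spec))
        labels = spec.dynamics.region_labels
        # rgb is (R, G, B); expected dominant channel per drive frequency
        for region, channel in [(1, 2), (2, 1), (3, 0)]:
            means = img.rgb[:, labels == region].mean(axis=1)
            assert np.argmax(means) == channel, (region, means)

    def test_static_stack_renders_dark(self):
        stack = simulate_stack(static_sample_spec())
        with pytest.warns(UserWarning, match="constant channel"):
            img = dynamic_pipeline(stack)
        assert img.std_map.max() == 0.0
        np.testing.assert_array_equal(img.rgb, 0.0)

    def test_deterministic_rerun(self):
        stack = simulate_stack(three_band_spec(seed=4, shape=(32, 32), n_frames=128))
        a = dynamic_pipeline(stack)
        b = dynamic_pipeline(stack)
        np.testing.assert_array_equal(a.rgb, b.rgb)
        np.testing.assert_array_equal(a.std_map, b.std_map)

    def test_band_power_monotone_in_drive_amplitude(self):
        # raising a region's drive amplitude raises its pre-render band power
        powers = []
        for amp in (2.0, 5.0, 10.0):
            spec = three_band_spec(seed=1, shape=(32, 32), n_frames=256,
                                   amplitude_nm=amp)
            img = dynamic_pipeline(simulate_stack(spec))
            labels = spec.dynamics.region_labels
            powers.append(img.band_maps[1][labels == 2].mean())
        assert powers[0] < powers[1] < powers[2]


class TestMeanSpectrumAndVolume:
    def test_mean_spectrum_averages_pixels(self, noise_stack):
        cube = pixel_spectrum(noise_stack)
        np.testing.assert_allclose(mean_spectrum(cube),
                                   cube.magnitudes.mean(axis=(1, 2)))

    def test_two_pixel_mean_is_half_sum(self):
        t = 64
        series = np.cos(2 * np.pi * 8 * np.arange(t) / t) + 2.0
        frames = np.zeros((t, 1, 2))  # second pixel identically dark
        frames[:, 0, 0] = series
        cube = pixel_spectrum(make_stack(frames))
        single = cube.magnitudes[:, 0, 0]
        np.testing.assert_allclose(mean_spectrum(cube), single / 2, atol=1e-12)

    def test_volume_single_plane_projections(self):
        img = dynamic_pipeline(simulate_stack(three_band_spec(0, (32, 32), 128)))
        vol = assemble_volume([img], z_step_um=1.0)
        assert vol.volume.shape == (3, 1, 32, 32)
        np.testing.assert_array_equal(vol.projection_xy, img.rgb)

    def test_max_projection_ignores_dark_plane(self):
        img = dynamic_pipeline(simulate_stack(three_band_spec(0, (32, 32), 128)))
        with pytest.warns(UserWarning, match="constant channel"):
            dark = dynamic_pipeline(simulate_stack(static_sample_spec(0, (32, 32), 128)))
        vol = assemble_volume([img, dark], z_step_um=0.5)
        np.testing.assert_array_equal(vol.projection_xy, img.rgb)

    def test_red_layer_appears_at_its_z_row(self):
        bright = dynamic_pipeline(simulate_stack(three_band_spec(0, (32, 32), 128)))
        with pytest.warns(UserWarning, match="constant channel"):
            dark = dynamic_pipeline(simulate_stack(static_sample_spec(0, (32, 32), 128)))
        vol = assemble_volume([dark, bright, dark], z_step_um=1.0)
        red_xz = vol.projection_xz[0]  # (Z, X)
        per_plane_red = vol.volume[0].max(axis=(1, 2))
        assert np.argmax(per_plane_red) == 1
        assert red_xz[1].max() > 0
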