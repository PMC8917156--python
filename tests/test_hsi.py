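"""Cube I/O, spectral slicing, 2D localization and depth-from-width."""

import numpy as np
import pytest

from dsli import hsi
from dsli.hsi import CalibrationCurve, HyperspectralCube, IntensityMap


def small_cube(seed=0, dtype=np.uint16):
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 4000, size=(8, 8, 16)).astype(dtype)
    return HyperspectralCube(
        x_um=np.arange(8) * 5.0, y_um=np.arange(8) * 5.0,
        wavelength_nm=500.0 + 0.023 * np.arange(16), data=data)


def gaussian_map(x0=60.0, y0=50.0, sx=20.0, sy=20.0, amp=1000.0,
                 offset=0.0, extent=120.0, pitch=2.5, theta=0.0):
    ax = np.arange(0.0, extent + pitch / 2, pitch)
    X, Y = np.meshgrid(ax, ax)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (X - x0) * ct + (Y - y0) * st
    yr = -(X - x0) * st + (Y - y0) * ct
    data = amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + offset
    return IntensityMap(ax, ax, data)


class TestCubeIO:
    def test_hdf5_round_trip_bit_exact(self, tmp_path):
        cube = small_cube()
        p = tmp_path / "c.h5"
        hsi.write_cube(cube, p)
        back = hsi.read_cube(p)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.wavelength_nm, cube.wavelength_nm)

    @pytest.mark.parametrize("interleave", ["bsq", "bil"])
    def test_envi_round_trip(self, tmp_path, interleave):
        cube = small_cube()
        p = tmp_path / f"c_{interleave}.hdr"
        hsi.write_cube(cube, p, format="envi", interleave=interleave)
        back = hsi.read_cube(p, format="envi")
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.wavelength_nm, cube.wavelength_nm,
                                   atol=1e-5)
        np.testing.assert_allclose(back.x_um, cube.x_um)

    def test_envi_interleaves_agree(self, tmp_path):
        cube = small_cube()
        hsi.write_cube(cube, tmp_path / "a.hdr", "envi", "bsq")
        hsi.write_cube(cube, tmp_path / "b.hdr", "envi", "bil")
        a = hsi.read_cube(tmp_path / "a.hdr", "envi")
        b = hsi.read_cube(tmp_path / "b.hdr", "envi")
        np.testing.assert_array_equal(a.data, b.data)

    def test_missing_wavelength_metadata_raises(self, tmp_path):
        cube = small_cube()
        p = tmp_path / "c.hdr"
        hsi.write_cube(cube, p, format="envi")
        text = p.read_text()
        p.write_text("\n".join(line for line in text.splitlines()
                               if not line.startswith("wavelength =")))
        with pytest.raises(ValueError, match="wavelength"):
            hsi.read_cube(p, format="envi")

    def test_map_export(self, tmp_path):
        m = gaussian_map()
        hsi.write_map(m, tmp_path / "m")
        import tifffile

        img = tifffile.imread(tmp_path / "m.tif")
        assert img.dtype == np.uint16
        assert img.shape == m.data.shape
        assert (tmp_path / "m.csv").exists()

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            HyperspectralCube(np.arange(4.0), np.arange(8.0),
                              np.arange(16.0), np.zeros((8, 5, 16)))


class TestSpectralOps:
    def test_single_nonzero_pixel(self):
        cube = small_cube()
        cube.data = np.zeros_like(cube.data)
        cube.data[3, 4, :] = np.arange(16)
        s = hsi.spectral_sum(cube)
        np.testing.assert_allclose(s.intensity, np.arange(16))

    def test_region_linearity(self):
        cube = small_cube()
        cube.data = np.ones_like(cube.data)
        mask = np.zeros((8, 8), dtype=bool)
        mask[:3, :2] = True
        s = hsi.spectral_sum(cube, mask)
        np.testing.assert_allclose(s.intensity, 6.0)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            hsi.spectral_sum(small_cube(), np.zeros((8, 8), dtype=bool))

    def test_band_outside_grid_raises(self):
        with pytest.raises(ValueError):
            hsi.slice_at_peak(small_cube(), 499.0, 0.1)

    def test_gap_band_is_noise_floor(self):
        rng = np.random.default_rng(1)
        lam = 500.0 + 0.023 * np.arange(400)
        data = np.zeros((10, 10, 400))
        # one emitter with a single line at 502
        line = 1000.0 * (0.037**2) / ((lam - 502.0) ** 2 + 0.037**2)
        data += line[None, None, :] * np.exp(
            -0.5 * (((np.arange(10)[:, None] - 5) ** 2
                     + (np.arange(10)[None, :] - 5) ** 2) / 9.0))[:, :, None]
        cube = HyperspectralCube(np.arange(10) * 5.0, np.arange(10) * 5.0,
                                 lam, data + rng.normal(0, 1, data.shape))
        gap = hsi.slice_at_peak(cube, 506.0, 0.069)
        on = hsi.slice_at_peak(cube, 502.0, 0.069)
        assert np.abs(gap.data).max() < 0.02 * on.data.max()

    def test_binning_commutes_with_localization(self):
        m = gaussian_map()
        cube_data = m.data[:, :, None] * np.ones(8)[None, None, :]
        cube = HyperspectralCube(m.x_um, m.y_um,
                                 500.0 + 0.023 * np.arange(8), cube_data)
        binned = hsi.bin_cube(cube, 2, 2)
        loc_full = hsi.fit_gaussian2d(
            hsi.slice_at_peak(cube, 500.08, 0.08, sideband=False))
        loc_bin = hsi.fit_gaussian2d(
            hsi.slice_at_peak(binned, 500.08, 0.08, sideband=False))
        assert abs(loc_full.x0_um - loc_bin.x0_um) < 1.0
        assert abs(loc_full.y0_um - loc_bin.y0_um) < 1.0


class TestGaussian2D:
    def test_exact_recovery(self):
        m = gaussian_map(x0=63.0, y0=48.5, sx=18.0, sy=25.0, offset=50.0)
        loc = hsi.fit_gaussian2d(m)
        assert loc.status == "ok"
        assert abs(loc.x0_um - 63.0) < 1e-6
        assert abs(loc.y0_um - 48.5) < 1e-6
        assert abs(loc.sigma_x_um - 18.0) < 1e-5 or \
            abs(loc.sigma_x_um - 25.0) < 1e-5  # orientation degeneracy

    def test_poisson_noise_center_within_tenth_pixel(self):
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(100):
            m = gaussian_map(amp=100.0)  # peak SNR ~ 10
            noisy = IntensityMap(m.x_um, m.y_um,
                                 rng.poisson(m.data).astype(float))
            loc = hsi.fit_gaussian2d(noisy)
            errs.append(np.hypot(loc.x0_um - 60.0, loc.y0_um - 50.0))
        assert np.mean(errs) < 0.25  # 0.1 pixel at 2.5 um pitch

    def test_double_blob_flagged_not_midpoint(self):
        a = gaussian_map(x0=40.0, y0=60.0, sx=12.0, sy=12.0)
        b = gaussian_map(x0=76.0, y0=60.0, sx=12.0, sy=12.0)
        m = IntensityMap(a.x_um, a.y_um, a.data + b.data)
        loc = hsi.fit_gaussian2d(m)
        midpoint = abs(loc.x0_um - 58.0) < 3.0
        assert loc.status == "poor" or not midpoint


class TestMultiPeakAveraging:
    def test_averaging_beats_single_peak(self):
        """Combining many per-resonance fits reduces the center error
        versus any single resonance slice (paired over seeds)."""
        rng = np.random.default_rng(13)
        ax = np.arange(0.0, 161.0, 5.0)
        lam = 500.0 + 0.023 * np.arange(60)
        X, Y = np.meshgrid(ax, ax)
        blob = np.exp(-0.5 * (((X - 70.0) ** 2 + (Y - 90.0) ** 2) / 40.0**2))
        teeth = lam[5:55:6]  # 9 resonances
        spectrum = np.zeros_like(lam)
        for t in teeth:
            spectrum += 60.0 * 0.037**2 / ((lam - t) ** 2 + 0.037**2)
        clean = blob[:, :, None] * spectrum[None, None, :]

        class G:
            members = [type("P", (), {"wavelength_nm": t, "amplitude": 1.0})()
                       for t in teeth]

        single_err, multi_err = [], []
        for _ in range(8):
            cube = HyperspectralCube(ax, ax, lam,
                                     rng.poisson(clean).astype(float))
            loc = hsi.localize_microcavity(cube, G())
            multi_err.append(np.hypot(loc.x0_um - 70.0, loc.y0_um - 90.0))
            one = hsi.fit_gaussian2d(
                hsi.slice_at_peak(cube, teeth[4], 0.07), fit_offset=False)
            single_err.append(np.hypot(one.x0_um - 70.0, one.y0_um - 90.0))
        ratio = np.mean(single_err) / np.mean(multi_err)
        print(f"multi-peak averaging improves localization {ratio:.1f}x")
        assert np.mean(multi_err) < np.mean(single_err)


class TestSurfaceWidth:
    def test_isotropic_gaussian(self):
        m = gaussian_map(x0=60, y0=60, sx=20.0, sy=20.0, extent=240.0)
        w = hsi.surface_width(m)
        assert abs(w - 20.0) < 0.2

    def test_anisotropic_matches_direction_fits(self):
        m = gaussian_map(x0=120, y0=120, sx=20.0, sy=30.0, extent=240.0)
        w = hsi.surface_width(m, n_directions=4)
        # direction sigmas: 20, 30 on axes; sqrt(2/(1/sx^2+1/sy^2)) diagonal
        diag = np.sqrt(2.0 / (1 / 400 + 1 / 900))
        expected = (20.0 + 30.0 + 2 * diag) / 4
        assert abs(w - expected) < 0.5

    def test_intensity_rescaling_invariance(self):
        m = gaussian_map(x0=60, y0=60, extent=120.0)
        m2 = IntensityMap(m.x_um, m.y_um, 37.5 * m.data)
        assert abs(hsi.surface_width(m) - hsi.surface_width(m2)) < 1e-6

    def test_fwhm_metric(self):
        m = gaussian_map(x0=60, y0=60, sx=20.0, sy=20.0, extent=240.0)
        w = hsi.surface_width(m, metric="fwhm")
        assert abs(w - 20.0 * 2.3548) < 0.5

    def test_flat_map_raises(self):
        m = IntensityMap(np.arange(10.0), np.arange(10.0), np.ones((10, 10)))
        with pytest.raises(ValueError):
            hsi.surface_width(m)


class TestDepthFromWidth:
    CAL = CalibrationCurve(depth_um=[50, 150, 250, 350, 450],
                           width_um=[40, 90, 150, 220, 300])

    def test_knot_queries(self):
        for d, w in zip(self.CAL.depth_um, self.CAL.width_um):
            assert abs(hsi.depth_from_width(w, self.CAL) - d) < 1e-9

    def test_monotone_between_knots(self):
        ws = np.linspace(41, 299, 60)
        ds = [hsi.depth_from_width(w, self.CAL) for w in ws]
        assert np.all(np.diff(ds) > 0)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            d = hsi.depth_from_width(1000.0, self.CAL)
        assert d == pytest.approx(450.0)

    def test_non_monotone_calibration_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(depth_um=[50, 150, 250],
                             width_um=[40, 120, 100])
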