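"""Mie optics and photon-transport Monte Carlo."""

import numpy as np
import pytest
from scipy import stats

from dsli import mc
from dsli.mc import McGeometry, MieScatterer, OpticalMedium


PHANTOM = OpticalMedium(63.0, 0.2, 0.87, 1.41)


class TestTransportLength:
    def test_high_scattering_phantom(self):
        l_star, _ = mc.transport_length(OpticalMedium(76.0, 0.2, 0.87, 1.41))
        assert abs(l_star - 100.0) < 1.0

    def test_standard_phantom(self):
        l_star, _ = mc.transport_length(PHANTOM)
        assert abs(l_star - 120.0) < 1.0

    def test_isotropic_no_absorption_limit(self):
        med = OpticalMedium(10.0, 0.0, 0.0, 1.4)
        l_star, ls = mc.transport_length(med)
        assert l_star == pytest.approx(ls) == pytest.approx(100.0)

    def test_degenerate_medium_signalled(self):
        with pytest.raises(ValueError):
            mc.transport_length(OpticalMedium(0.0, 0.0, 0.0, 1.4))


class TestMie:
    def test_polystyrene_in_pdms_anisotropy(self):
        sc = MieScatterer(0.51, 1.60, 1.41, wavelength_nm=532.0)
        _, g = mc.mie_single_particle(sc)
        assert abs(g - 0.87) < 0.01

    def test_rayleigh_limit(self):
        sc = MieScatterer(0.01, 1.60, 1.33, wavelength_nm=532.0)
        _, g = mc.mie_single_particle(sc)
        assert abs(g) < 0.02

    def test_phase_table_mean_cos_matches_series_g(self):
        sc = MieScatterer(0.51, 1.60, 1.41, wavelength_nm=532.0)
        _, g = mc.mie_single_particle(sc)
        mu, cdf = mc.mie_phase_table(sc)
        g_tab = np.trapezoid(mu * np.gradient(cdf, mu), mu)
        assert abs(g_tab - g) < 0.01

    def test_tabulated_sampler_matches_g(self):
        sc = MieScatterer(0.51, 1.60, 1.41, wavelength_nm=532.0)
        sigma, g = mc.mie_single_particle(sc)
        med = OpticalMedium(10.0, 0.0, g, 1.41, phase_function="mie",
                            phase_table=mc.mie_phase_table(sc))
        ct = mc.sample_scatter_angle(med, np.random.default_rng(3), 200_000)
        assert abs(ct.mean() - g) < 0.01 * max(abs(g), 1.0)

    def test_medium_from_particles_linearity(self):
        sc1 = MieScatterer(0.51, 1.60, 1.41, number_density_per_mm3=1e6)
        sc2 = MieScatterer(0.51, 1.60, 1.41, number_density_per_mm3=2e6)
        m1 = mc.medium_from_particles(sc1)
        m2 = mc.medium_from_particles(sc2)
        assert m2.mus_per_mm == pytest.approx(2 * m1.mus_per_mm)
        assert m2.g == pytest.approx(m1.g)

    def test_zero_density_zero_scattering(self):
        sc = MieScatterer(0.51, 1.60, 1.41, number_density_per_mm3=0.0)
        assert mc.medium_from_particles(sc).mus_per_mm == 0.0

    def test_density_for_phantom_mus(self):
        """Solve the density that reproduces the phantom's mu_s = 63/mm."""
        sc0 = MieScatterer(0.51, 1.60, 1.41, number_density_per_mm3=1.0)
        sigma, _ = mc.mie_single_particle(sc0)
        density = 63.0 / (sigma * 1e-6)
        med = mc.medium_from_particles(
            MieScatterer(0.51, 1.60, 1.41, number_density_per_mm3=density))
        assert med.mus_per_mm == pytest.approx(63.0, rel=1e-9)


class TestScatterSampling:
    def test_isotropic_hg_uniform_cos(self):
        med = OpticalMedium(10.0, 0.0, 0.0, 1.4)
        ct = mc.sample_scatter_angle(med, np.random.default_rng(5), 100_000)
        _, p = stats.kstest(ct, stats.uniform(loc=-1, scale=2).cdf)
        assert p > 1e-3

    def test_hg_moment_matches_g(self):
        med = OpticalMedium(10.0, 0.0, 0.87, 1.4)
        ct = mc.sample_scatter_angle(med, np.random.default_rng(6), 200_000)
        assert abs(ct.mean() - 0.87) < 0.002


class TestTransport:
    def test_vacuum_matched_boundaries_full_transmission(self):
        med = OpticalMedium(0.0, 0.0, 0.0, 1.0)
        geo = McGeometry("embedded", thickness_um=100.0, source_depth_um=0.0,
                         n_above=1.0, n_below=1.0)
        res = mc.run_mc(med, geo, n_photons=2000, seed=4, source="pencil")
        assert res.exit_bottom == pytest.approx(1.0)
        assert res.ballistic_bottom == pytest.approx(1.0)

    def test_ballistic_beer_lambert(self):
        med = OpticalMedium(20.0, 0.5, 0.0, 1.0)
        geo = McGeometry("embedded", thickness_um=100.0, source_depth_um=0.0,
                         n_above=1.0, n_below=1.0)
        n = 200_000
        res = mc.run_mc(med, geo, n_photons=n, seed=4, source="pencil")
        expected = np.exp(-(20.0 + 0.5) * 1e-3 * 100.0)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(res.ballistic_bottom - expected) < 4 * sigma

    def test_energy_conservation(self):
        geo = McGeometry("embedded", thickness_um=500.0, source_depth_um=250.0,
                         n_below=1.34)
        res = mc.run_mc(PHANTOM, geo, n_photons=20_000, seed=3)
        assert res.energy_budget == pytest.approx(1.0, abs=1e-9)

    def test_seeded_determinism(self):
        geo = McGeometry("slab_overlayer", thickness_um=200.0,
                         source_depth_um=200.0)
        a = mc.run_mc(PHANTOM, geo, n_photons=5000, seed=11)
        b = mc.run_mc(PHANTOM, geo, n_photons=5000, seed=11)
        np.testing.assert_array_equal(a.surface_map.data, b.surface_map.data)
        assert a.exit_top == b.exit_top

    def test_embedded_footprint_wider_than_overlayer(self):
        l_star, _ = mc.transport_length(PHANTOM)
        depth = 2.3 * l_star
        over = mc.run_mc(
            PHANTOM, McGeometry("slab_overlayer", thickness_um=depth,
                                source_depth_um=depth, n_below=1.34),
            n_photons=150_000, seed=11, map_half_um=1000.0)
        emb = mc.run_mc(
            PHANTOM, McGeometry("embedded", thickness_um=depth + 5 * l_star,
                                source_depth_um=depth, n_below=1.34),
            n_photons=150_000, seed=12, map_half_um=1000.0)
        from dsli.hsi import surface_width

        w_over = surface_width(over.surface_map)
        w_emb = surface_width(emb.surface_map)
        assert w_emb > w_over
        print(f"embedded footprint wider by "
              f"{100 * (w_emb / w_over - 1):.1f}%")

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            McGeometry("slab_overlayer", thickness_um=100.0,
                       source_depth_um=150.0)


class TestCalibration:
    def test_widths_increase_with_depth(self):
        curve = mc.build_calibration(
            PHANTOM, [60.0, 140.0, 220.0, 300.0], n_photons=60_000, seed=2)
        assert np.all(np.diff(curve.width_um) > 0)

    def test_two_seeds_agree(self):
        depths = [80.0, 160.0, 240.0]
        c1 = mc.build_calibration(PHANTOM, depths, n_photons=80_000, seed=1)
        c2 = mc.build_calibration(PHANTOM, depths, n_photons=80_000, seed=99)
        assert np.all(np.abs(c1.width_um - c2.width_um)
                      / c1.width_um < 0.10)

    def test_depth_width_round_trip(self):
        """depth -> simulated footprint -> width -> depth closes."""
        from dsli.hsi import depth_from_width, surface_width

        curve = mc.build_calibration(
            PHANTOM, [60.0, 120.0, 180.0, 240.0, 300.0],
            n_photons=80_000, seed=5, map_half_um=900.0)
        probe_depth = 150.0
        res = mc.run_mc(
            PHANTOM, McGeometry("slab_overlayer", thickness_um=probe_depth,
                                source_depth_um=probe_depth, n_below=1.34),
            n_photons=80_000, seed=777, map_half_um=900.0)
        w = surface_width(res.surface_map)
        d = depth_from_width(w, curve)
        assert abs(d - probe_depth) < 25.0  # within interpolation + MC noise


class TestIntegratingSphere:
    def test_thin_slab_limit(self):
        """A vanishing slab leaves only the two Fresnel faces."""
        med = OpticalMedium(30.0, 0.2, 0.87, 1.41)
        t, r = mc.integrating_sphere_rt(med, 0.01, n_photons=50_000, seed=1)
        r1 = ((1.41 - 1.0) / (1.41 + 1.0)) ** 2
        r_both = 2 * r1 / (1 + r1)  # incoherent double-interface sum
        assert abs(r - r_both) < 0.01
        assert abs(t - (1 - r_both)) < 0.01

    def test_energy_budget(self):
        t, r = mc.integrating_sphere_rt(PHANTOM, 200.0, n_photons=20_000,
                                        seed=2)
        assert 0 < t < 1 and 0 < r < 1 and t + r < 1

    def test_transmittance_decreases_with_thickness(self):
        ts = [mc.integrating_sphere_rt(PHANTOM, L, n_photons=30_000,
                                       seed=3)[0]
              for L in (50.0, 150.0, 300.0, 500.0)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_mua_sweep_smooth_and_monotone(self):
        """Absorption drains both R and T smoothly (common random numbers)."""
        ts, rs = [], []
        for mua in (0.0, 0.2, 0.5, 1.0, 2.0):
            med = OpticalMedium(63.0, mua, 0.87, 1.41)
            t, r = mc.integrating_sphere_rt(med, 170.0, n_photons=40_000,
                                            seed=7)
            ts.append(t)
            rs.append(r)
        assert all(a > b for a, b in zip(ts, ts[1:]))
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_inversion_round_trip(self):
        """Inversion recovers the transport-identifiable mu_s(1-g).

        R and T of one slab constrain the reduced scattering coefficient
        tightly but leave a flat valley along it, so the individual (mu_s,
        g) optimum may sit anywhere on the valley (including the search
        edge); the valley position itself must close the round trip.
        """
        t_meas, r_meas = mc.integrating_sphere_rt(
            PHANTOM, 170.0, n_photons=100_000, seed=10)
        mus, g, resid, status = mc.invert_optical_properties(
            r_meas, t_meas, 170.0,
            mus_range_per_mm=(53.0, 73.0), g_range=(0.82, 0.92),
            n_photons=40_000, seed=20, n_grid=(5, 5), n=1.41)
        musp_true = 63.0 * (1 - 0.87)
        assert abs(mus * (1 - g) - musp_true) < 1.5
        assert resid.min() < 1e-3

    def test_inconsistent_measurement_hits_boundary(self):
        _, _, _, status = mc.invert_optical_properties(
            0.9, 0.05, 170.0, mus_range_per_mm=(40.0, 60.0),
            g_range=(0.8, 0.9), n_photons=4000, seed=1, n_grid=(3, 3))
        assert status == "boundary"
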