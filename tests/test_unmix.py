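"""Peak detection, background removal and FSR comb unmixing."""

import numpy as np
import pytest

from conftest import make_comb
from dsli import unmix
from dsli.unmix import Peak, Spectrum


def lorentz(lam, center, fwhm, amp):
    return amp * (0.5 * fwhm) ** 2 / ((lam - center) ** 2 + (0.5 * fwhm) ** 2)


GRID = np.arange(500.0, 540.0, 0.023)


def comb_spectrum(teeth, q=7000.0, amp=1000.0, background=0.0, noise=0.0,
                  seed=0):
    rng = np.random.default_rng(seed)
    y = background * np.exp(-0.5 * ((GRID - 515.0) / 30.0) ** 2)
    for t in teeth:
        y += lorentz(GRID, t, t / q, amp)
    if noise:
        y = y + rng.normal(0, noise, len(GRID))
    return Spectrum(GRID, y)


class TestBackgroundSubtraction:
    def test_pure_smooth_background_removed(self):
        s = comb_spectrum([], background=500.0)
        out = unmix.subtract_background(s)
        interior = slice(50, -50)
        assert np.abs(out.intensity[interior]).max() < 0.03 * 500.0

    def test_flat_zero_input(self):
        s = Spectrum(GRID, np.zeros_like(GRID))
        out = unmix.subtract_background(s)
        assert np.abs(out.intensity).max() < 1e-9

    def test_peak_amplitudes_preserved(self):
        teeth = make_comb(1e3 / 520.0, 0.0130)
        clean = comb_spectrum(teeth)  # ground-truth comb, no background
        s = comb_spectrum(teeth, background=500.0)
        out = unmix.subtract_background(s)
        for t in teeth[1:-1]:
            i = np.argmin(np.abs(GRID - t))
            assert (abs(out.intensity[i] - clean.intensity[i])
                    / clean.intensity[i] < 0.05)

    def test_short_spectrum_raises(self):
        with pytest.raises(ValueError):
            unmix.subtract_background(Spectrum(GRID[:8], np.zeros(8)))


class TestDetectPeaks:
    def test_single_lorentzian_center_subresolution(self):
        s = comb_spectrum([520.0])  # fwhm 0.074 nm at Q 7000
        peaks = unmix.detect_peaks(s, prominence_threshold=100.0)
        assert len(peaks) == 1
        assert abs(peaks[0].wavelength_nm - 520.0) < 0.001
        assert abs(peaks[0].fwhm_nm - 520.0 / 7000.0) < 0.005
        assert abs(peaks[0].quality_factor - 7000.0) < 500.0

    def test_two_well_separated_lorentzians(self):
        s = comb_spectrum([519.0, 519.0 + 5 * 0.074])
        peaks = unmix.detect_peaks(s, 100.0)
        assert len(peaks) == 2
        assert abs(peaks[0].wavelength_nm - 519.0) < 0.005
        assert abs(peaks[1].wavelength_nm - 519.37) < 0.005

    def test_nothing_above_threshold(self):
        s = comb_spectrum([], noise=1.0)
        assert unmix.detect_peaks(s, 1000.0) == []


def brute_force_fsr(peaks, tol, fsr_range):
    """Independent exhaustive implementation of FSR-by-propagation."""
    lam = np.array([p.wavelength_nm for p in peaks])
    nu = 1.0 / (lam * 1e-3)
    out = np.full(len(peaks), np.nan)
    sup = np.zeros(len(peaks), dtype=int)
    for i in range(len(peaks)):
        best = (0, np.nan)
        for j in range(len(peaks)):
            if i == j:
                continue
            f = abs(nu[i] - nu[j])
            if not fsr_range[0] <= f <= fsr_range[1]:
                continue
            count = 0
            for k in range(len(peaks)):
                n_near = round((nu[k] - nu[i]) / f)
                if abs(nu[k] - nu[i] - n_near * f) < tol:
                    count += 1
            if count > best[0] or (count == best[0] and f < best[1]):
                best = (count, f)
        if best[0] >= 4:
            out[i], sup[i] = best[1], best[0]
    return out, sup


class TestAssignFsr:
    def test_single_perfect_comb(self):
        teeth = make_comb(1e3 / 520.0, 0.0130)[:10]
        peaks = [Peak(w, 0.074, 100, 1000) for w in teeth]
        fsr, support = unmix.assign_fsr(peaks)
        np.testing.assert_allclose(fsr, 0.0130, atol=1e-6)
        assert np.all(support == 10)

    def test_matches_brute_force_on_two_combs(self, two_comb_peaks):
        peaks, labels, fsr1, fsr2 = two_comb_peaks
        tol = unmix.default_match_tolerance(
            float(np.mean([p.wavelength_nm for p in peaks])))
        ours_f, ours_s = unmix.assign_fsr(peaks)
        brute_f, brute_s = brute_force_fsr(peaks, tol, (0.009, 0.025))
        np.testing.assert_allclose(ours_f, brute_f, atol=1e-9)
        np.testing.assert_array_equal(ours_s, brute_s)
        for f, lbl in zip(ours_f, labels):
            assert abs(f - (fsr1 if lbl == "a" else fsr2)) < 1e-4

    def test_three_incommensurate_peaks_unassigned(self):
        peaks = [Peak(w, 0.074, 100, 1000) for w in (505.0, 517.3, 531.9)]
        fsr, support = unmix.assign_fsr(peaks)
        assert np.all(np.isnan(fsr))

    def test_fewer_than_three_peaks(self):
        peaks = [Peak(510.0, 0.074, 100, 1000), Peak(514.0, 0.074, 100, 1000)]
        fsr, _ = unmix.assign_fsr(peaks)
        assert np.all(np.isnan(fsr))


class TestGrouping:
    def test_two_combs_two_groups(self, two_comb_peaks):
        peaks, labels, fsr1, fsr2 = two_comb_peaks
        fsr, support = unmix.assign_fsr(peaks)
        groups = unmix.group_peaks(peaks, fsr, support)
        assert len(groups) == 2
        by_fsr = sorted(groups, key=lambda g: g.fsr_per_um)
        for g, want in zip(by_fsr, ("a", "b")):
            got = {labels[peaks.index(p)] for p in g.members}
            assert got == {want}

    def test_five_sphere_scene_five_groups(self):
        """Five well-separated beads render >60 peaks that unmix cleanly."""
        from dsli import wgm

        diameters = [13.1, 14.0, 15.05, 16.2, 17.4]
        teeth, truth = [], []
        for d in diameters:
            ms = wgm.find_modes(wgm.SphereParams(d, 1.59, 1.34),
                                (500, 540), 1)
            teeth.extend(ms.wavelengths())
            truth.append(set(np.round(ms.wavelengths(), 4)))
        s = comb_spectrum(sorted(teeth))
        peaks = unmix.detect_peaks(s, 100.0)
        assert len(peaks) > 60
        fsr, support = unmix.assign_fsr(peaks)
        groups = unmix.group_peaks(peaks, fsr, support)
        merged = unmix.pair_te_tm(groups)
        big = [g for g in merged if len(g.members) >= 6]
        assert len(big) == 5
        # each group maps to one distinct bead; most members lie on that
        # bead's truth comb (a few foreign teeth coincide with the comb
        # within tolerance and are legitimately shared)
        matched_beads = set()
        for g in big:
            dists = np.array([[min(abs(np.array(sorted(t)) - p.wavelength_nm))
                               for p in g.members] for t in truth])
            owner = int(np.argmin(np.median(dists, axis=1)))
            matched_beads.add(owner)
            assert np.mean(dists[owner] < 0.03) >= 0.85
        assert matched_beads == set(range(5))

    def test_nearly_equal_diameters_merge(self):
        """Combs of two beads 2 nm apart land on the same detected peaks."""
        from dsli import wgm

        t1 = wgm.find_modes(wgm.SphereParams(15.000, 1.59, 1.34),
                            (500, 540), 1).wavelengths()
        t2 = wgm.find_modes(wgm.SphereParams(15.002, 1.59, 1.34),
                            (500, 540), 1).wavelengths()
        s = comb_spectrum(sorted(np.concatenate([t1, t2])))
        peaks = unmix.detect_peaks(s, 100.0)
        fsr, support = unmix.assign_fsr(peaks)
        merged = unmix.pair_te_tm(unmix.group_peaks(peaks, fsr, support))
        assert len([g for g in merged if len(g.members) >= 6]) == 1


class TestPairTeTm:
    def test_te_tm_pair_merges(self):
        te = make_comb(1e3 / 520.0, 0.0133)[:8]
        tm = make_comb(1e3 / 521.5, 0.0133)[:8]
        peaks = [Peak(w, 0.074, 100, 1000)
                 for w in np.sort(np.concatenate([te, tm]))]
        fsr, support = unmix.assign_fsr(peaks)
        groups = unmix.group_peaks(peaks, fsr, support)
        assert len(groups) == 2
        merged = unmix.pair_te_tm(groups)
        assert len(merged) == 1
        assert set(merged[0].polarizations) == {"TE", "TM"}

    def test_single_polarization_passes_through(self):
        te = make_comb(1e3 / 520.0, 0.0133)[:8]
        peaks = [Peak(w, 0.074, 100, 1000) for w in te]
        fsr, support = unmix.assign_fsr(peaks)
        groups = unmix.group_peaks(peaks, fsr, support)
        merged = unmix.pair_te_tm(groups)
        assert len(merged) == len(groups) == 1

    def test_solver_check_rejects_inconsistent_pair(self):
        """Two accidental same-FSR combs do not fit one sphere's equation."""
        c1 = make_comb(1e3 / 520.0, 0.0133)[:8]
        c2 = make_comb(1e3 / 520.9, 0.0133)[:8]  # arbitrary phase offset
        peaks = [Peak(w, 0.074, 100, 1000)
                 for w in np.sort(np.concatenate([c1, c2]))]
        fsr, support = unmix.assign_fsr(peaks)
        groups = unmix.group_peaks(peaks, fsr, support)
        merged = unmix.pair_te_tm(groups, verify_n_internal=1.59)
        assert len(merged) == 2  # merge rejected by the characteristic fit


class TestFillMissing:
    def test_deleted_tooth_predicted(self):
        teeth = make_comb(1e3 / 520.0, 0.0130)[:10]
        kept = np.delete(teeth, 3)
        peaks = [Peak(w, 0.074, 100, 1000) for w in kept]
        g = unmix.PeakGroup(0, 0.0130, list(peaks), ["TE"] * len(peaks))
        g = unmix.fill_missing_peaks(g, (teeth[0] - 1.0, teeth[-1] + 1.0))
        assert len(g.filled_in) >= 1
        assert min(abs(np.array(g.filled_in) - teeth[3])) < 0.02

    def test_complete_comb_nothing_filled(self):
        teeth = make_comb(1e3 / 520.0, 0.0130)[:10]
        peaks = [Peak(w, 0.074, 100, 1000) for w in teeth]
        g = unmix.PeakGroup(0, 0.0130, list(peaks), ["TE"] * len(peaks))
        g = unmix.fill_missing_peaks(g, (teeth[0] - 0.5, teeth[-1] + 0.5))
        assert g.filled_in == []

    def test_two_member_group_predicts_rest(self):
        teeth = make_comb(1e3 / 520.0, 0.0130)[:10]
        peaks = [Peak(w, 0.074, 100, 1000) for w in teeth[:2]]
        g = unmix.PeakGroup(0, 0.0130, list(peaks), ["TE", "TE"])
        g = unmix.fill_missing_peaks(g, (teeth[0] - 0.5, teeth[-1] + 0.5))
        assert len(g.filled_in) == 8

    def test_reconstructed_comb_self_consistent(self, two_comb_peaks):
        peaks, labels, fsr1, fsr2 = two_comb_peaks
        fsr, support = unmix.assign_fsr(peaks)
        groups = unmix.group_peaks(peaks, fsr, support)
        for g in groups:
            unmix.fill_missing_peaks(g, (500.0, 540.0))
            nus = 1.0 / (np.concatenate([
                [p.wavelength_nm for p in g.members], g.filled_in]) * 1e-3)
            tol = unmix.default_match_tolerance(520.0)
            dev = (nus - nus[0] + g.fsr_per_um / 2) % g.fsr_per_um \
                - g.fsr_per_um / 2
            assert np.all(np.abs(dev) < tol)
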