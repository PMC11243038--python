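"""Spectra engine: FC laws, SOS/oracle consistency, broadening, profiles."""

import dataclasses
import math

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from rrsolv import (convergence_curve, convolve_sticks, enhancement_factors,
                    ensemble_average, fc_matrix, fc_overlap, make_chromophore,
                    project_gradient, raman_spectrum, rr_cross_section,
                    rr_polarizability, rrep, td_oracle_polarizability,
                    uvvis_spectrum, absorption_lineshape, band_origin_cm,
                    shift_intensity_check)
from rrsolv.spectra import (Spectrum, TruncationWarning, average_sticks,
                            raman_activity_from_tensors, rr_stick_spectrum)
from rrsolv.units import EV_TO_CM, nm_to_cm


class TestFranckCondon:
    @pytest.mark.parametrize("S", [0.5, 1.0, 2.0])
    def test_poisson_law(self, S):
        F = fc_matrix(np.sqrt(2 * S), 0, 12)
        expected = [np.exp(-S) * S**m / math.factorial(m) for m in range(13)]
        npt.assert_allclose(F[0] ** 2, expected, atol=1e-12)

    def test_zero_displacement_identity(self):
        F = fc_matrix(0.0, 5, 5)
        npt.assert_allclose(F, np.eye(6), atol=1e-14)
        assert fc_overlap(0.0, 3, 3) == pytest.approx(1.0)
        assert fc_overlap(0.0, 2, 3) == pytest.approx(0.0)

    @pytest.mark.parametrize("S", [0.5, 1.0, 2.0])
    def test_completeness(self, S):
        # truncate where the Poisson tail drops below 1e-12
        m_max = 40
        F = fc_matrix(np.sqrt(2 * S), 0, m_max)
        assert abs((F[0] ** 2).sum() - 1.0) < 1e-10

    @given(st.floats(min_value=0.0, max_value=3.0))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_column_norms_bounded(self, S):
        F = fc_matrix(np.sqrt(2 * S), 8, 8)
        norms = (F**2).sum(axis=0)
        assert np.all(norms <= 1.0 + 1e-12)
        assert F[0, 0] == pytest.approx(np.exp(-S / 2))

    def test_large_quanta_log_domain(self):
        v = fc_overlap(1.0, 0, 200)
        assert np.isfinite(v)
        assert v == pytest.approx(np.exp(-0.5 + 100 * np.log(1.0)
                                         - 0.5 * math.lgamma(201)), rel=1e-10)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            fc_overlap(-0.1, 0, 0)
        with pytest.raises(ValueError):
            fc_overlap(1.0, -1, 0)


class TestRRPolarizability:
    def test_zero_displacement_zero_amplitude(self):
        m = make_chromophore(4, 2, n_states=1, seed=1,
                             displacements=np.zeros((1, 2)))
        a = rr_polarizability(m, m.states[0], 0, 38000.0, 200.0)
        assert a == 0

    def test_silent_mode_factorizes_out(self):
        m2 = make_chromophore(4, 2, n_states=1, seed=2,
                              displacements=np.array([[0.8, 0.0]]),
                              freqs_cm=[1200.0, 1500.0],
                              state_energies_cm=[39000.0], osc_strengths=[0.3])
        m1 = make_chromophore(4, 1, n_states=1, seed=2,
                              displacements=np.array([[0.8]]),
                              freqs_cm=[1200.0],
                              state_energies_cm=[39000.0], osc_strengths=[0.3])
        a2 = rr_polarizability(m2, m2.states[0], 0, 38500.0, 200.0)
        a1 = rr_polarizability(m1, m1.states[0], 0, 38500.0, 200.0)
        assert abs(a2 - a1) / abs(a1) < 1e-10

    def test_ti_matches_td_oracle(self, three_mode_model):
        m = three_mode_model
        for w0 in (34000.0, 39000.0):
            ti = rr_polarizability(m, m.states[0], 1, w0, 200.0)
            td = td_oracle_polarizability(m, m.states[0], 1, w0, 200.0)
            assert abs(ti - td) / abs(td) < 1e-6

    def test_td_damping_monotone_decay(self, single_mode_model):
        m = single_mode_model
        mags = [abs(td_oracle_polarizability(m, m.states[0], 0, 39300.0, g))
                for g in (200.0, 400.0, 800.0, 1600.0)]
        assert np.all(np.diff(mags) < 0)

    def test_truncation_warning_on_tight_budget(self):
        m = make_chromophore(4, 1, n_states=1, seed=3,
                             displacements=np.array([[2.5]]))  # S ~ 3.1
        with pytest.warns(TruncationWarning):
            rr_polarizability(m, m.states[0], 0, 38000.0, 200.0, max_quanta=2)

    def test_invalid_gamma(self, single_mode_model):
        m = single_mode_model
        with pytest.raises(ValueError):
            rr_polarizability(m, m.states[0], 0, 38000.0, 0.0)


class TestCrossSection:
    def test_quadratic_in_dipole(self):
        a = 0.3 + 0.1j
        assert rr_cross_section(2 * a, 37594.0, 1400.0) == pytest.approx(
            4 * rr_cross_section(a, 37594.0, 1400.0))

    def test_frequency_factor_ratio(self):
        a = 1.0 + 0.0j
        w = 1400.0
        w266, w1064 = nm_to_cm(266.0), nm_to_cm(1064.0)
        ratio = rr_cross_section(a, w266, w) / rr_cross_section(a, w1064, w)
        expected = (w266 * (w266 - w) ** 3) / (w1064 * (w1064 - w) ** 3)
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_scattered_frequency_rejected(self):
        with pytest.raises(ValueError):
            rr_cross_section(1.0, 1000.0, 1400.0)


class TestRamanSpectrum:
    def test_silent_mode_zero_stick(self):
        m = make_chromophore(4, 2, seed=1)
        m = dataclasses.replace(m, alpha_deriv=np.array([0.0, 0.5]),
                                gamma_deriv=np.array([0.0, 0.2]))
        spec = raman_spectrum(m)
        assert spec.intensities[0] == 0.0
        assert spec.intensities[1] > 0.0

    def test_invariant_combination_equivalence(self):
        # gamma'² = (45/7) a'² gives the same activity as isotropic-only
        m = make_chromophore(4, 2, seed=2, freqs_cm=[1200.0, 1300.0])
        a = 0.4
        m = dataclasses.replace(
            m, alpha_deriv=np.array([a, 0.0]),
            gamma_deriv=np.array([0.0, np.sqrt(45.0 / 7.0) * a]))
        spec = raman_spectrum(m)
        w0 = spec.w0_cm
        activities = (spec.intensities * m.freqs_cm
                      / (w0 * (w0 - m.freqs_cm) ** 3))
        assert activities[0] == pytest.approx(activities[1])

    def test_invariants_rotation_invariant(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=(3, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a0, g0 = raman_activity_from_tensors(t)
        a1, g1 = raman_activity_from_tensors(q @ t @ q.T)
        assert a1 == pytest.approx(a0, abs=1e-10)
        assert g1 == pytest.approx(g0, abs=1e-9)


class TestUVVis:
    def test_single_state_gaussian_shape(self):
        fwhm_cm = 0.6 * EV_TO_CM
        grid = np.linspace(30000, 45000, 30001)
        spec = uvvis_spectrum([[(37500.0, 0.5)]], 0.6, grid_cm=grid)
        imax = np.argmax(spec.intensities)
        assert abs(spec.axis[imax] - 37500.0) < 1.0
        half = np.interp(37500.0 + fwhm_cm / 2, spec.axis, spec.intensities)
        assert half == pytest.approx(spec.intensities[imax] / 2, rel=1e-3)

    def test_two_identical_snapshots_average_unchanged(self):
        snaps = [[(37000.0, 0.2)], [(37000.0, 0.2)]]
        avg, members = uvvis_spectrum(snaps, return_members=True)
        npt.assert_allclose(avg.intensities, members[0].intensities)

    def test_inhomogeneous_broadening_quadrature(self):
        # Gaussian jitter of the stick position convolves widths:
        # FWHM_total = sqrt(FWHM² + (2.3548 sigma)²)
        rng = np.random.default_rng(7)
        sigma = 2000.0
        snaps = [[(40000.0 + rng.normal(scale=sigma), 0.3)]
                 for _ in range(4000)]
        grid = np.linspace(20000, 60000, 8001)
        spec = uvvis_spectrum(snaps, 0.6, grid_cm=grid)
        y = spec.intensities / spec.intensities.max()
        above = spec.axis[y >= 0.5]
        measured = above[-1] - above[0]
        expected = np.hypot(0.6 * EV_TO_CM, 2.3548 * sigma)
        assert measured == pytest.approx(expected, rel=0.02)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            uvvis_spectrum([])


class TestConvolution:
    def _one_stick(self):
        return Spectrum(axis=np.array([1000.0]), intensities=np.array([2.0]),
                        kind="raman", is_sticks=True)

    @pytest.mark.parametrize("shape", ["lorentzian", "gaussian"])
    def test_half_maximum_at_half_fwhm(self, shape):
        conv = convolve_sticks(self._one_stick(), shape, 8.0, points=160001)
        imax = np.argmax(conv.intensities)
        half = np.interp(1004.0, conv.axis, conv.intensities)
        assert half == pytest.approx(conv.intensities[imax] / 2, rel=1e-3)

    def test_area_conserved(self):
        sticks = Spectrum(axis=np.array([1000.0, 1300.0]),
                          intensities=np.array([2.0, 5.0]),
                          kind="raman", is_sticks=True)
        conv = convolve_sticks(sticks, "gaussian", 8.0, points=20000)
        area = np.trapezoid(conv.intensities, conv.axis)
        assert area == pytest.approx(7.0, rel=1e-3)

    def test_resolved_doublet(self):
        sticks = Spectrum(axis=np.array([1000.0, 1050.0]),
                          intensities=np.array([1.0, 1.0]),
                          kind="raman", is_sticks=True)
        conv = convolve_sticks(sticks, "lorentzian", 8.0, points=8000)
        step = conv.axis[1] - conv.axis[0]
        y = conv.intensities
        peaks = conv.axis[1:-1][(y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])]
        assert len(peaks) == 2
        assert abs(peaks[0] - 1000.0) <= step and abs(peaks[1] - 1050.0) <= step

    def test_grid_auto_extension(self, caplog):
        import logging
        with caplog.at_level(logging.INFO, logger="rrsolv.spectra"):
            conv = convolve_sticks(self._one_stick(), "lorentzian", 8.0,
                                   grid_cm=np.linspace(995, 1005, 50))
        assert conv.axis.min() <= 1000 - 80
        assert any("extending" in r.message for r in caplog.records)


class TestAveraging:
    def _sticks(self, inten, axis=(1000.0, 1200.0)):
        return Spectrum(axis=np.array(axis), intensities=np.array(inten),
                        kind="raman", is_sticks=True, labels=("a", "b"))

    def test_identical_members_mean_unchanged(self):
        s = self._sticks([1.0, 2.0])
        avg = ensemble_average([s, s, s])
        npt.assert_array_equal(avg.intensities, s.intensities)
        assert avg.n_averaged == 3

    def test_mean_of_offsets_recovers_baseline(self):
        b = np.array([5.0, 5.0])
        d = np.array([1.5, -2.0])
        avg = ensemble_average([self._sticks(b + d), self._sticks(b - d)])
        npt.assert_allclose(avg.intensities, b)

    def test_one_hot_members_uniform_mean(self):
        n = 4
        axis = tuple(1000.0 + 50.0 * k for k in range(n))
        members = []
        for k in range(n):
            inten = np.zeros(n)
            inten[k] = 1.0
            members.append(Spectrum(axis=np.array(axis), intensities=inten,
                                    kind="raman", is_sticks=True))
        avg = ensemble_average(members)
        npt.assert_allclose(avg.intensities, 1.0 / n)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([self._sticks([1, 2]),
                              self._sticks([1, 2], axis=(999.0, 1200.0))])

    def test_average_sticks_mode_matched(self):
        a = self._sticks([1.0, 3.0])
        b = Spectrum(axis=np.array([1010.0, 1190.0]),
                     intensities=np.array([3.0, 5.0]), kind="raman",
                     is_sticks=True, labels=("a", "b"))
        avg = average_sticks([a, b])
        npt.assert_allclose(avg.axis, [1005.0, 1195.0])
        npt.assert_allclose(avg.intensities, [2.0, 4.0])

    def test_average_commutes_with_convolution(self):
        a, b = self._sticks([1.0, 2.0]), self._sticks([3.0, 1.0])
        grid = np.linspace(900, 1300, 2001)
        path1 = convolve_sticks(ensemble_average([a, b]), "lorentzian", 8.0,
                                grid_cm=grid)
        path2 = ensemble_average([
            convolve_sticks(s, "lorentzian", 8.0, grid_cm=grid)
            for s in (a, b)])
        npt.assert_allclose(path1.intensities, path2.intensities, rtol=1e-12)


class TestConvergence:
    def test_identical_ensemble_similarity_one(self):
        s = Spectrum(axis=np.linspace(0, 10, 50),
                     intensities=np.exp(-np.linspace(0, 10, 50)), kind="uvvis")
        cc = convergence_curve([s] * 6)
        npt.assert_allclose(cc["similarity"], 1.0, atol=1e-12)

    def test_similarity_one_at_full_ensemble(self):
        rng = np.random.default_rng(5)
        ax = np.linspace(0, 10, 64)
        members = [Spectrum(axis=ax, intensities=rng.uniform(0.1, 1, 64),
                            kind="uvvis") for _ in range(8)]
        cc = convergence_curve(members)
        assert cc["similarity"].iloc[-1] == pytest.approx(1.0, abs=1e-12)

    def test_needs_two_spectra(self):
        s = Spectrum(axis=np.linspace(0, 1, 5), intensities=np.ones(5),
                     kind="uvvis")
        with pytest.raises(ValueError):
            convergence_curve([s])


class TestProfilesAndLineshape:
    def test_zero_delta_flat_zero_profile(self):
        m = make_chromophore(4, 2, n_states=1, seed=6,
                             displacements=np.zeros((1, 2)))
        prof = rrep([m], np.linspace(35000, 45000, 5), 200.0)
        npt.assert_array_equal(prof.cross_sections, 0.0)

    def test_rrep_argmax_tracks_absorption_maximum(self, single_mode_model):
        m = single_mode_model
        ab = absorption_lineshape(m, m.states[0], 200.0,
                                  grid_cm=np.linspace(36000, 46000, 4000))
        w_abs = ab.axis[np.argmax(ab.intensities)]
        grid = np.linspace(37000, 43000, 15)
        prof = rrep([m], grid, 200.0)
        w_rr = grid[np.argmax(prof.cross_sections[0])]
        assert abs(w_rr - w_abs) <= grid[1] - grid[0]

    def test_rrep_damping_lowers_and_broadens(self, single_mode_model):
        m = single_mode_model
        grid = np.linspace(37000, 43000, 15)
        p1 = rrep([m], grid, 200.0).cross_sections[0]
        p2 = rrep([m], grid, 400.0).cross_sections[0]
        assert p2.max() < p1.max()
        assert p2.max() / p2.min() < p1.max() / p1.min()  # flatter profile

    def test_rrep_grid_below_mode_frequency_rejected(self, single_mode_model):
        with pytest.raises(ValueError):
            rrep([single_mode_model], np.linspace(500, 40000, 5), 200.0)

    def test_absorption_zero_delta_single_lorentzian(self):
        m = make_chromophore(4, 1, n_states=1, seed=7,
                             displacements=np.zeros((1, 1)),
                             state_energies_cm=[40000.0])
        spec = absorption_lineshape(m, m.states[0], 200.0)
        assert abs(spec.axis[np.argmax(spec.intensities)] - 40000.0) < 10.0

    def test_absorption_poisson_peak_ratio_s1(self):
        # S = 1: the 0-0 and 0-1 vibronic lines carry equal FC weight
        m = make_chromophore(4, 1, n_states=1, seed=8,
                             displacements=np.array([[np.sqrt(2.0)]]),
                             freqs_cm=[1400.0], state_energies_cm=[40000.0])
        eps00 = band_origin_cm(m, m.states[0])
        grid = np.linspace(eps00 - 1000, eps00 + 3000, 16001)
        spec = absorption_lineshape(m, m.states[0], 30.0, grid_cm=grid,
                                    max_quanta=14)
        y_per_photon = spec.intensities / spec.axis
        i00 = np.interp(eps00, spec.axis, y_per_photon)
        i01 = np.interp(eps00 + 1400.0, spec.axis, y_per_photon)
        assert i01 == pytest.approx(i00, rel=0.01)

    def test_absorption_area_gamma_independent(self):
        m = make_chromophore(4, 1, n_states=1, seed=9,
                             displacements=np.array([[0.8]]),
                             freqs_cm=[1400.0], state_energies_cm=[40000.0])
        eps00 = band_origin_cm(m, m.states[0])
        grid = np.linspace(max(eps00 - 60000, 100), eps00 + 70000, 120001)
        areas = []
        for g in (100.0, 200.0):
            spec = absorption_lineshape(m, m.states[0], g, grid_cm=grid)
            areas.append(np.trapezoid(spec.intensities / spec.axis, spec.axis))
        assert areas[0] == pytest.approx(areas[1], rel=0.005)


class TestEnhancement:
    def _sticks(self, inten, w0, labels=("a", "b", "c")):
        return Spectrum(axis=np.array([1000.0, 1200.0, 1400.0]),
                        intensities=np.asarray(inten, float), kind="rr",
                        w0_cm=w0, is_sticks=True, labels=labels)

    def test_identical_spectra_unit_factors(self):
        s = self._sticks([1.0, 2.0, 3.0], 37594.0)
        rep = enhancement_factors(s, s)
        npt.assert_allclose(rep.factors, 1.0)

    def test_zero_raman_flagged_nan(self):
        rep = enhancement_factors(self._sticks([1.0, 2.0, 3.0], 37594.0),
                                  self._sticks([2.0, 0.0, 3.0], 9398.5))
        assert np.isnan(rep.factors[1])
        assert np.isfinite(rep.factors[[0, 2]]).all()

    def test_prefactor_invariance(self):
        rr = self._sticks([1.0, 2.0, 3.0], 37594.0)
        ra = self._sticks([0.5, 0.4, 0.1], 9398.5)
        f1 = enhancement_factors(rr, ra).factors
        c = 1e-20
        f2 = enhancement_factors(
            dataclasses.replace(rr, intensities=c * rr.intensities),
            dataclasses.replace(ra, intensities=c * ra.intensities)).factors
        npt.assert_allclose(f1, f2, rtol=1e-12)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enhancement_factors(self._sticks([1, 2, 3], 1.0),
                                self._sticks([1, 2, 3], 1.0,
                                             labels=("a", "b", "z")))


class TestShiftIntensity:
    def test_pre_resonance_short_time_limit(self):
        # far below resonance the fundamental amplitudes follow
        # omega_k Delta_k (hence |alpha|² ~ omega² Delta²) mode by mode
        m = make_chromophore(5, 4, n_states=1, seed=10,
                             displacements=np.array([[0.3, -0.6, 0.45, 0.8]]),
                             freqs_cm=[1100.0, 1300.0, 1500.0, 1700.0],
                             state_energies_cm=[42000.0], osc_strengths=[0.3])
        st_ = m.states[0]
        w0 = 10000.0
        alpha2 = np.array([abs(rr_polarizability(m, st_, j, w0, 200.0)) ** 2
                           for j in range(4)])
        sticks = Spectrum(axis=m.freqs_cm, intensities=alpha2, kind="rr",
                          w0_cm=w0, is_sticks=True)
        disp = project_gradient(st_, m)
        rep = shift_intensity_check(disp, sticks,
                                    band_origin=band_origin_cm(m, st_))
        assert rep.pre_resonance
        assert rep.spearman_rho == 1.0
        ratios = alpha2 / rep.weights
        assert ratios.max() / ratios.min() - 1 < 0.05

    def test_degenerate_ranking_reported_as_ties(self):
        m = make_chromophore(5, 3, n_states=1, seed=11,
                             displacements=np.array([[0.5, 0.5, 0.5]]),
                             freqs_cm=[1400.0, 1400.0, 1400.0])
        disp = project_gradient(m.states[0], m)
        sticks = Spectrum(axis=m.freqs_cm, intensities=np.ones(3), kind="rr",
                          w0_cm=30000.0, is_sticks=True)
        rep = shift_intensity_check(disp, sticks)
        assert rep.undefined_by_ties
        assert np.isnan(rep.spearman_rho)

    def test_too_few_modes_rejected(self, single_mode_model):
        m = single_mode_model
        disp = project_gradient(m.states[0], m)
        sticks = rr_stick_spectrum(m, m.states[0], 39000.0, 200.0)
        with pytest.raises(ValueError):
            shift_intensity_check(disp, sticks)
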