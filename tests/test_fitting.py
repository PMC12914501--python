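"""Classical quantification: B0 correction, Lorentzian fits, PLOF,
polynomial reference, mfit-poly, Δpoly and the three-point APT metric."""

import numpy as np
import pytest

from guancest import fitting
from guancest.bmc import default_tissue, simulate_zspectrum
from guancest.fitting import (
    LorentzianPeak,
    MultiPoolFit,
    PolyCoeffs,
    apt_three_point,
    delta_poly,
    estimate_and_correct_b0,
    estimate_b0_shift,
    lorentzian,
    lorentzian_multipool_fit,
    mfit_poly_amines,
    plof_fit,
    poly_reference_quantify,
    quantify_from_fit,
)
from guancest.physics import (
    AcquisitionScheme,
    RexSpectrum,
    WaterMTParams,
    ZSpectrum,
    arex,
    cos2_theta,
    reff,
)


def _zspec(scheme, z, r1obs=0.6, fm=0.1):
    return ZSpectrum(scheme.offsets_ppm, z, r1obs=r1obs, fm=fm)


def _compact_bump(offs, amplitude, center, half_width):
    """Raised-cosine peak that is exactly zero beyond ``half_width``.

    Unlike a Lorentzian it has no tails, so it genuinely vanishes inside
    the masked background-fit windows.
    """
    d = np.abs(np.asarray(offs) - center)
    return np.where(d < half_width, amplitude * 0.5 * (1 + np.cos(np.pi * d / half_width)), 0.0)


class TestB0:
    def test_zero_shift_estimated_as_tiny(self, scheme):
        z = simulate_zspectrum(default_tissue(), scheme)
        assert abs(estimate_b0_shift(z)) < 0.02

    def test_simulated_shift_recovered(self, scheme):
        z = simulate_zspectrum(default_tissue(), scheme, b0_shift_ppm=0.1)
        assert estimate_b0_shift(z) == pytest.approx(0.1, abs=0.02)

    def test_correction_inverts_shift_on_smooth_spectra(self, scheme):
        z0 = simulate_zspectrum(default_tissue(), scheme)
        z1 = simulate_zspectrum(default_tissue(), scheme, b0_shift_ppm=0.08)
        zc = estimate_and_correct_b0(z1)
        inner = np.abs(scheme.offsets_ppm) <= 4.0
        assert np.max(np.abs(zc.z[inner] - z0.z[inner])) < 0.01


class TestMultipoolFit:
    def test_flat_spectrum_gives_no_solute_amplitudes(self, scheme):
        z = _zspec(scheme, np.ones(scheme.n_offsets))
        fit = lorentzian_multipool_fit(z, "6pool")
        for name, pk in fit.peaks.items():
            if name != "water":
                assert pk.amplitude < 1e-3

    def test_exact_six_lorentzian_sum_recovered(self, scheme):
        truth = {
            "water": (0.85, 0.02, 1.8),
            "amide": (0.04, 3.52, 1.1),
            "amines_guan": (0.08, 2.4, 3.2),
            "noe16": (0.03, -1.62, 1.2),
            "noe35": (0.09, -3.55, 2.8),
            "mt": (0.10, -1.2, 42.0),
        }
        total = np.zeros(scheme.n_offsets)
        for a, c, w in truth.values():
            total += lorentzian(scheme.offsets_ppm, a, c, w)
        fit = lorentzian_multipool_fit(_zspec(scheme, 1.0 - total), "6pool")
        for name, (a, c, w) in truth.items():
            pk = fit.peaks[name]
            assert pk.amplitude == pytest.approx(a, rel=0.01), name
            assert pk.center_ppm == pytest.approx(c, abs=0.02), name
            assert pk.width_ppm == pytest.approx(w, rel=0.01), name
        assert fit.residual_rms < 1e-6

    def test_six_pool_amines_guan_broader_than_seven_pool_guan(self, scheme, default_ranges):
        from guancest.bmc import generate_tissue_mimicking_set

        z, _ = generate_tissue_mimicking_set(default_ranges, 1, seed=13, scheme=scheme)[0]
        zc = estimate_and_correct_b0(z)
        f6 = lorentzian_multipool_fit(zc, "6pool")
        f7 = lorentzian_multipool_fit(zc, "7pool")
        assert f6.peaks["amines_guan"].width_ppm >= f7.peaks["guan"].width_ppm


class TestQuantifyFromFit:
    def _toy_fit(self, scheme):
        peaks = {
            "water": LorentzianPeak(0.8, 0.0, 1.8),
            "guan": LorentzianPeak(0.06, 2.0, 0.8),
        }
        z = 1.0 - peaks["water"](scheme.offsets_ppm) - peaks["guan"](scheme.offsets_ppm)
        return _zspec(scheme, z), MultiPoolFit(peaks, 0.0, "toy")

    def test_zero_amplitude_target_gives_zero_spectrum(self, scheme):
        z, fit = self._toy_fit(scheme)
        fit.peaks["guan"] = LorentzianPeak(0.0, 2.0, 0.8)
        z = _zspec(scheme, 1.0 - fit.peaks["water"](scheme.offsets_ppm))
        r = quantify_from_fit(z, fit, "guan")
        assert np.allclose(r.values, 0.0, atol=1e-12)

    def test_matches_inversion_subtraction_closed_form(self, scheme):
        z, fit = self._toy_fit(scheme)
        r = quantify_from_fit(z, fit, "guan")
        s_ref = 1.0 - fit.peaks["water"](r.offsets_ppm)
        s_lab = s_ref - fit.peaks["guan"](r.offsets_ppm)
        expected = (1.0 / s_lab - 1.0 / s_ref) * z.r1obs * (1.0 + z.fm)
        assert np.max(np.abs(r.values - expected)) < 1e-10

    def test_missing_pool_raises(self, scheme):
        z, fit = self._toy_fit(scheme)
        with pytest.raises(KeyError):
            quantify_from_fit(z, fit, "amide")


class TestPLOF:
    def _plof_forward(self, scheme, amp, width, r1obs=0.6, fm=0.1, r2w=18.0):
        offs = scheme.offsets_ppm
        bg = PolyCoeffs(0.25, -0.02, 0.01, -0.002)(offs)
        den = reff(offs, scheme, r1obs, r2w) + lorentzian(offs, amp, 2.0, width) + bg
        z = r1obs * cos2_theta(offs, scheme) / den
        return _zspec(scheme, z, r1obs=r1obs, fm=fm)

    def test_self_inverse_recovery(self, scheme):
        z = self._plof_forward(scheme, amp=0.12, width=0.7)
        spec = plof_fit(z, scheme=scheme)
        at2 = np.isclose(spec.offsets_ppm, 2.0)
        expected = 0.12 * 1.1 / cos2_theta(np.array([2.0]), scheme)[0]
        assert spec.values[at2][0] == pytest.approx(expected, rel=0.02)

    def test_zero_guanidine_fits_below_noise_floor(self, scheme):
        z = self._plof_forward(scheme, amp=0.0, width=0.7)
        spec = plof_fit(z, scheme=scheme)
        assert np.max(np.abs(spec.values)) < 0.01

    def test_requires_r1obs_metadata(self, scheme):
        z = ZSpectrum(scheme.offsets_ppm, np.full(scheme.n_offsets, 0.8))
        with pytest.raises(ValueError):
            plof_fit(z, scheme=scheme)


class TestPolyReference:
    def test_exactly_cubic_background_gives_zero(self, scheme):
        z = 0.8 + 0.01 * (scheme.offsets_ppm - 2.0) - 0.004 * (scheme.offsets_ppm - 2.0) ** 3
        r = poly_reference_quantify(_zspec(scheme, z))
        assert np.max(np.abs(r.values)) < 1e-10

    def test_narrow_dip_recovered_on_cubic_background(self, scheme):
        offs = scheme.offsets_ppm
        bg = 0.8 + 0.01 * (offs - 2.0) - 0.004 * (offs - 2.0) ** 3
        dip = _compact_bump(offs, 0.05, 2.0, 0.45)  # vanishes inside the fit windows
        z = _zspec(scheme, bg - dip)
        r = poly_reference_quantify(z)
        at2 = np.isclose(r.offsets_ppm, 2.0)
        s_ref = bg[np.isclose(offs, 2.0)][0]
        expected = (1.0 / (s_ref - 0.05) - 1.0 / s_ref) * z.r1obs * (1.0 + z.fm)
        assert r.values[at2][0] == pytest.approx(expected, rel=0.05)
        assert r.values[at2][0] == pytest.approx(expected, abs=0.003)

    def test_underdetermined_windows_rejected(self):
        sch = AcquisitionScheme(offsets_ppm=[1.2, 2.0, 2.7], control_offset_ppm=333.0)
        z = ZSpectrum(sch.offsets_ppm, np.array([0.8, 0.7, 0.8]), r1obs=0.6, fm=0.1)
        with pytest.raises(ValueError):
            poly_reference_quantify(z)


class TestMfitPolyAndDeltaPoly:
    def test_exact_cubic_recovered_to_machine_precision(self, scheme):
        offs = scheme.offsets_ppm
        truth = PolyCoeffs(0.5, 0.1, -0.03, 0.01)
        coeffs, spec = mfit_poly_amines(RexSpectrum(offs, truth(offs), "ag"))
        for got, want in zip((coeffs.c0, coeffs.c1, coeffs.c2, coeffs.c3), (0.5, 0.1, -0.03, 0.01)):
            assert got == pytest.approx(want, abs=1e-12)

    def test_guanidine_bump_excluded_by_windows(self, scheme):
        offs = scheme.offsets_ppm
        truth = PolyCoeffs(0.5, 0.1, -0.03, 0.01)
        bump = _compact_bump(offs, 0.2, 2.0, 0.45)
        coeffs, _ = mfit_poly_amines(RexSpectrum(offs, truth(offs) + bump, "ag"))
        for got, want in zip((coeffs.c0, coeffs.c1, coeffs.c2, coeffs.c3), (0.5, 0.1, -0.03, 0.01)):
            assert got == pytest.approx(want, rel=0.02, abs=1e-9)

    def test_zero_input_gives_zero_coefficients(self, scheme):
        coeffs, spec = mfit_poly_amines(RexSpectrum(scheme.offsets_ppm, np.zeros(scheme.n_offsets), "ag"))
        assert coeffs(np.array([1.0, 2.0, 4.0])) == pytest.approx([0.0, 0.0, 0.0], abs=1e-14)

    def test_delta_poly_is_exact_subtraction(self, scheme):
        offs = scheme.offsets_ppm
        cubic = PolyCoeffs(0.5, 0.1, -0.03, 0.01)(offs)
        bump = lorentzian(offs, 0.2, 2.0, 0.4)
        d = delta_poly(RexSpectrum(offs, cubic + bump, "ag"), RexSpectrum(offs, cubic, "amines"))
        assert np.allclose(d.values, bump, atol=1e-14)

    def test_delta_poly_grid_mismatch_rejected(self):
        a = RexSpectrum(np.array([1.0, 2.0]), np.array([0.1, 0.2]), "ag")
        b = RexSpectrum(np.array([1.0, 3.0]), np.array([0.1, 0.2]), "amines")
        with pytest.raises(ValueError):
            delta_poly(a, b)


class TestAptThreePoint:
    def test_flat_signals_give_zero(self, scheme):
        z = _zspec(scheme, np.full(scheme.n_offsets, 0.6))
        assert apt_three_point(z) == 0.0

    def test_hand_value_with_mean_reference(self, scheme):
        z = np.full(scheme.n_offsets, 0.62)
        z[np.isclose(scheme.offsets_ppm, 3.0)] = 0.60
        z[np.isclose(scheme.offsets_ppm, 3.5)] = 0.58
        z[np.isclose(scheme.offsets_ppm, 4.0)] = 0.64
        # S_ref = mean(0.60, 0.64) = 0.62 -> (1/0.58 - 1/0.62)*0.5*1.1
        val = apt_three_point(_zspec(scheme, z, r1obs=0.5, fm=0.1))
        assert val == pytest.approx((1 / 0.58 - 1 / 0.62) * 0.55, abs=1e-12)
        assert val == pytest.approx(0.061182, abs=1e-5)

    def test_linear_z_cancels(self, scheme):
        z = 0.9 - 0.05 * scheme.offsets_ppm
        assert abs(apt_three_point(_zspec(scheme, z))) < 1e-12

    def test_missing_offsets_without_interpolation_rejected(self):
        sch = AcquisitionScheme(offsets_ppm=[3.1, 3.6, 3.9], control_offset_ppm=333.0)
        z = ZSpectrum(sch.offsets_ppm, np.array([0.6, 0.58, 0.63]), r1obs=0.5, fm=0.1)
        with pytest.raises(ValueError):
            apt_three_point(z, interpolate=False)
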