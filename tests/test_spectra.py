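"""Spectrum construction, derivatives, peak finding, classification and
nonnegative unmixing."""

import numpy as np
import pytest

from hemekin.spectra import (
    Band,
    SORET_WINDOW,
    Spectrum,
    build_reference,
    classify_state,
    deconvolve,
    default_grid,
    find_band_maxima,
    second_derivative,
)

from conftest import simplex_grid_deconvolve


class TestSpectrumInvariants:
    def test_rejects_non_increasing_wavelengths(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([350.0, 350.0, 351.0]), np.zeros(3))

    def test_rejects_nonfinite_absorbance(self):
        with pytest.raises(ValueError, match="finite"):
            Spectrum(np.array([350.0, 351.0]), np.array([0.0, np.nan]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(350.0, 360.0), np.zeros(5))


class TestBuildReference:
    def test_ferric_h69l_global_maximum_at_390(self, grid):
        bands = [Band(390, 14, 100), Band(504, 22, 10), Band(637, 22, 9)]
        ref = build_reference(bands, grid)
        assert ref.wavelengths[np.argmax(ref.absorbance)] == 390.0

    def test_empty_band_list_gives_zero_spectrum(self, grid):
        ref = build_reference([], grid)
        assert np.all(ref.absorbance == 0.0)

    def test_single_band_value_and_maximum(self):
        grid = default_grid(350, 700, 1.0)
        ref = build_reference([Band(435, 12, 100)], grid)
        i = np.argmin(np.abs(ref.wavelengths - 435))
        assert ref.absorbance[i] == pytest.approx(100.0)
        assert ref.wavelengths[np.argmax(ref.absorbance)] == 435.0

    def test_sum_of_gaussians_pointwise(self, grid):
        bands = [Band(422, 14, 100), Band(436, 14, 60)]
        ref = build_reference(bands, grid)
        expected = sum(b.profile(grid) for b in bands)
        np.testing.assert_allclose(ref.absorbance, expected, rtol=0, atol=1e-12)
        assert np.all(ref.absorbance >= 0)

    def test_band_outside_grid_rejected_naming_band(self, grid):
        with pytest.raises(ValueError, match="720"):
            build_reference([Band(720, 14, 10)], grid)

    def test_maximum_near_largest_band_center(self, lib):
        # single dominant Soret: apex at the band center (+- 1 step);
        # overlapping Soret components: apex between the component centers
        for entry in lib:
            if not entry.bands:
                continue
            ref = lib.reference(entry.species_id)
            peak = ref.wavelengths[np.argmax(ref.absorbance)]
            soret_centers = [b.center for b in entry.bands
                             if SORET_WINDOW[0] <= b.center <= SORET_WINDOW[1]]
            if len(soret_centers) == 1:
                assert abs(peak - soret_centers[0]) <= 1.0, entry.species_id
            else:
                assert min(soret_centers) - 1 <= peak <= max(soret_centers) + 1, \
                    entry.species_id


class TestSecondDerivative:
    def test_single_gaussian_one_interior_minimum_at_center(self, grid):
        ref = build_reference([Band(435, 14, 100)], grid)
        d2 = second_derivative(ref.spectrum)
        y = d2.absorbance
        interior = np.where((y[1:-1] < y[:-2]) & (y[1:-1] < y[2:]))[0] + 1
        assert interior.size == 1
        assert abs(d2.wavelengths[interior[0]] - 435.0) <= 1.0

    def test_dual_soret_resolves_shoulder_as_two_minima(self, lib):
        # a 422-nm peak with a 436-nm shoulder: the absorbance shows one
        # maximum but the second derivative shows both components
        ref = lib.reference("AHb2_H66L_deoxy_acidic")
        assert find_band_maxima(ref.spectrum, (400, 460)) == [423.0]
        d2 = second_derivative(ref.spectrum)
        mask = (d2.wavelengths >= 400) & (d2.wavelengths <= 460)
        w, y = d2.wavelengths[mask], d2.absorbance[mask]
        minima = w[1:-1][(y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])]
        assert minima.size == 2
        assert abs(minima[0] - 422.0) <= 1.0
        assert abs(minima[1] - 436.0) <= 1.0

    def test_constant_spectrum_maps_to_zero(self, grid):
        d2 = second_derivative(Spectrum(grid, np.full(grid.size, 0.7)))
        assert np.max(np.abs(d2.absorbance)) < 1e-12

    def test_linear_spectrum_maps_to_zero(self, grid):
        d2 = second_derivative(Spectrum(grid, 0.01 * (grid - 350.0)))
        assert np.max(np.abs(d2.absorbance)) < 1e-9

    def test_short_spectrum_rejected(self):
        s = Spectrum(np.arange(400.0, 405.0), np.zeros(5))
        with pytest.raises(ValueError, match="window"):
            second_derivative(s, window=11)

    def test_even_window_rejected(self, grid):
        with pytest.raises(ValueError, match="odd"):
            second_derivative(Spectrum(grid, np.zeros(grid.size)), window=10)


class TestFindBandMaxima:
    def test_alkaline_deoxy_reference_three_peaks(self, lib):
        ref = lib.reference("AHb2_H66L_deoxy_alkaline")
        assert find_band_maxima(ref.spectrum, (400, 600)) == [422.0, 527.0, 557.0]

    def test_noiseless_single_band(self, grid):
        ref = build_reference([Band(435, 14, 1.0)], grid)
        assert find_band_maxima(ref.spectrum) == [435.0]

    def test_peak_location_robust_to_noise(self, grid):
        # oracle: argmax of the noiseless spectrum (435 nm)
        ref = build_reference([Band(435, 14, 1.0)], grid)
        rng = np.random.default_rng(20260921)
        hits = 0
        for _ in range(100):
            noisy = Spectrum(grid, ref.absorbance + 0.002 * rng.standard_normal(grid.size))
            peaks = find_band_maxima(noisy, (420, 450), min_prominence=0.05)
            if any(abs(p - 435.0) <= 1.0 for p in peaks):
                hits += 1
        assert hits >= 95

    def test_region_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="region"):
            find_band_maxima(Spectrum(grid, np.zeros(grid.size)), (300, 400))

    def test_empty_result_allowed(self, grid):
        assert find_band_maxima(Spectrum(grid, np.zeros(grid.size))) == []


class TestClassifyState:
    def test_pentacoordinate_ferric_charge_transfer(self):
        st = classify_state([390, 504, 637], "ferric")
        assert (st.ligation, st.spin) == ("five-coordinate", "high")
        assert st.sixth_ligand is None

    def test_hexacoordinate_low_spin_ferrous(self):
        st = classify_state([422, 527, 557], "ferrous")
        assert (st.ligation, st.spin) == ("six-coordinate", "low")
        assert st.sixth_ligand is not None

    def test_pentacoordinate_ferrous_deoxy(self):
        st = classify_state([435, 540, 569], "ferrous")
        assert (st.ligation, st.spin) == ("five-coordinate", "high")

    def test_no_soret_peak_is_indeterminate_not_exception(self):
        st = classify_state([527, 557], "ferrous")
        assert st.ligation == "indeterminate"
        assert "Soret" in st.note

    def test_fixture_rows_reproduce_expected_assignments(self, lib):
        checked = 0
        for entry in lib:
            if entry.expected_ligation is None:
                continue
            peaks = [b.center for b in entry.bands]
            st = classify_state(peaks, entry.oxidation)
            assert st.ligation == entry.expected_ligation, entry.species_id
            if entry.expected_spin is not None:
                assert st.spin == entry.expected_spin, entry.species_id
            checked += 1
        assert checked >= 10

    def test_pure_function(self):
        a = classify_state([435, 540, 569], "ferrous")
        b = classify_state([435, 540, 569], "ferrous")
        assert a == b


class TestDeconvolve:
    def _refs(self, lib):
        return [
            lib.reference("AHb1_H69L_deoxy"),
            lib.reference("AHb1_H69L_nitrosyl"),
            lib.reference("AHb1_H69L_ferric"),
        ]

    def test_identity_on_pure_reference(self, lib):
        refs = self._refs(lib)
        res = deconvolve(refs[0].spectrum, refs)
        np.testing.assert_allclose(res.fractions, [1.0, 0.0, 0.0], atol=1e-9)
        assert res.residual_norm < 1e-9

    def test_two_component_mixture_exact(self, lib):
        penta = lib.reference("deoxy_penta_component")
        hexa = lib.reference("deoxy_hexa_component")
        mix = Spectrum(penta.wavelengths, 0.4 * penta.absorbance + 0.6 * hexa.absorbance)
        res = deconvolve(mix, [penta, hexa])
        np.testing.assert_allclose(res.fractions, [0.4, 0.6], atol=1e-6)

    def test_agrees_with_simplex_grid_oracle(self, lib):
        penta = lib.reference("deoxy_penta_component")
        hexa = lib.reference("deoxy_hexa_component")
        mix = Spectrum(penta.wavelengths, 0.34 * penta.absorbance + 0.86 * hexa.absorbance)
        res = deconvolve(mix, [penta, hexa])
        oracle_c, _ = simplex_grid_deconvolve(mix, [penta, hexa], c_max=1.5, steps=76)
        np.testing.assert_allclose(res.coefficients, oracle_c, atol=0.02)

    def test_negative_component_clipped_to_zero(self, lib, grid):
        deoxy = lib.reference("AHb1_H69L_deoxy")
        ferric = lib.reference("AHb1_H69L_ferric")
        # a spectrum equal to deoxy MINUS some ferric: unconstrained LS
        # would want a negative ferric coefficient; NNLS returns 0
        s = Spectrum(grid, np.clip(deoxy.absorbance - 0.3 * ferric.absorbance, 0, None))
        res = deconvolve(s, [deoxy, ferric])
        assert res.coefficient("AHb1_H69L_ferric") == 0.0

    def test_grid_mismatch_rejected(self, lib):
        deoxy = lib.reference("AHb1_H69L_deoxy")
        other = lib.reference("AHb1_H69L_deoxy", default_grid(360, 690, 1.0))
        with pytest.raises(ValueError, match="grid"):
            deconvolve(deoxy.spectrum, [other])

    def test_all_zero_references_rejected(self, lib, grid):
        from hemekin.spectra import build_reference

        zero = build_reference([], grid)
        with pytest.raises(ValueError, match="zero"):
            deconvolve(Spectrum(grid, np.ones(grid.size)), [zero])

    def test_adding_reference_never_increases_residual(self, lib, grid):
        refs = self._refs(lib)
        rng = np.random.default_rng(7)
        s = Spectrum(grid, np.abs(0.5 * refs[0].absorbance + 0.01 * rng.standard_normal(grid.size)))
        r2 = deconvolve(s, refs[:2]).residual_norm
        r3 = deconvolve(s, refs).residual_norm
        assert r3 <= r2 + 1e-12

    def test_peak_and_derivative_minimum_agree_for_single_band(self, grid):
        for center in (390.0, 422.0, 435.0):
            ref = build_reference([Band(center, 14, 100)], grid)
            peak = find_band_maxima(ref.spectrum, SORET_WINDOW)[0]
            d2 = second_derivative(ref.spectrum)
            d2min = d2.wavelengths[np.argmin(d2.absorbance)]
            assert abs(peak - d2min) <= 1.0
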