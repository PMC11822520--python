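"""Calibration curves, empirical CDFs, and the Sigma-DeltaQCDF response."""

import numpy as np
import pytest

import sersquant as sq
from sersquant import calibration as cal
from sersquant.spectra import SpectralMap, Spectrum


def _spectrum(w, y):
    return Spectrum(np.asarray(w, float), np.asarray(y, float))


class TestMeanSpectrum:
    def test_single_spectrum_is_identity(self):
        s = _spectrum(np.arange(5.0), [1, 2, 3, 4, 5])
        m = cal.mean_spectrum([s])
        assert np.array_equal(m.intensities, s.intensities)

    def test_two_spectra_average(self):
        w = np.arange(5.0)
        m = cal.mean_spectrum([_spectrum(w, np.zeros(5)), _spectrum(w, np.full(5, 2.0))])
        assert np.array_equal(m.intensities, np.ones(5))

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            cal.mean_spectrum([])

    def test_mismatched_axes_raise(self):
        a = _spectrum(np.arange(5.0), np.zeros(5))
        b = _spectrum(np.arange(1.0, 6.0), np.zeros(5))
        with pytest.raises(sq.ConsistencyError):
            cal.mean_spectrum([a, b])

    def test_pooled_mean_weighted_by_spectrum_count(self, rng):
        w = np.arange(700.0, 800.0)
        m1 = SpectralMap("A1", w, np.zeros((3, w.size)), np.zeros((3, 2), int))
        m2 = SpectralMap("A2", w, np.ones((1, w.size)), np.zeros((1, 2), int))
        pooled = cal.pooled_mean_spectrum([m1, m2])
        assert np.allclose(pooled.intensities, 0.25)


class TestPeakResponse:
    def test_flat_spectrum_is_zero(self):
        s = _spectrum(np.arange(700.0, 800.0), np.full(100, 9.0))
        assert cal.peak_response(s) == 0.0

    def test_definitional_difference(self):
        w = np.arange(700.0, 800.0)
        y = np.zeros(100)
        y[w == 792.0] = 500.0
        y[w == 723.0] = 120.0
        assert cal.peak_response(_spectrum(w, y)) == 380.0

    def test_blank_subtraction_linearity(self, rng):
        w = np.arange(700.0, 800.0)
        a = _spectrum(w, rng.normal(size=100))
        blank = _spectrum(w, rng.normal(size=100))
        subtracted = _spectrum(w, a.intensities - blank.intensities)
        assert cal.peak_response(subtracted) == pytest.approx(
            cal.peak_response(a) - cal.peak_response(blank), rel=1e-12, abs=1e-12
        )


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = cal.linear_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response_convention(self):
        slope, intercept, r2 = cal.linear_regression(
            np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0])
        )
        assert (slope, intercept, r2) == (0.0, 5.0, 0.0)

    def test_constant_abscissa_raises(self):
        with pytest.raises(sq.RegressionError):
            cal.linear_regression(np.ones(3), np.arange(3.0))

    def test_matches_normal_equations_oracle(self, rng):
        x = np.linspace(0.0, 3.0, 7)
        y = 1.7 * x - 0.4 + rng.normal(0, 0.3, 7)
        slope, intercept, r2 = cal.linear_regression(x, y)
        # hand least squares via the normal equations
        n = x.size
        sxx = (x**2).sum() - x.sum() ** 2 / n
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        syy = (y**2).sum() - y.sum() ** 2 / n
        assert slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), abs=1e-12)
        assert r2 == pytest.approx(sxy**2 / (sxx * syy), abs=1e-12)


class TestTopKSelection:
    def _map(self, n=4):
        w = np.arange(700.0, 710.0)
        y = np.arange(n * w.size, dtype=float).reshape(n, w.size)
        coords = np.column_stack([np.zeros(n, int), np.arange(n)])
        return SpectralMap("A1", w, y, coords)

    def test_sorted_selection(self):
        smap = self._map()
        top = cal.select_top_k_by_qi(smap, np.array([5.0, 3.0, 9.0, 1.0]), 2)
        assert list(top.coordinates[:, 1]) == [2, 0]  # ranked 9, then 5

    def test_ties_keep_raster_order(self):
        smap = self._map()
        top = cal.select_top_k_by_qi(smap, np.array([5.0, 5.0, 5.0, 5.0]), 2)
        assert list(top.coordinates[:, 1]) == [0, 1]

    def test_k_equal_count_returns_whole_population(self):
        smap = self._map()
        top = cal.select_top_k_by_qi(smap, np.array([5.0, 3.0, 9.0, 1.0]), 4)
        assert top.n_spectra == 4

    @pytest.mark.parametrize("k", [0, -1, 5])
    def test_invalid_k_raises(self, k):
        smap = self._map()
        with pytest.raises(ValueError):
            cal.select_top_k_by_qi(smap, np.zeros(4), k)


class TestBuildCdf:
    def test_hand_sorted_example(self):
        cdf = cal.build_cdf(np.array([0.0, 2.0, 1.0, 0.0, 4.0]))
        assert np.allclose(cdf.x, np.log10([1.0, 2.0, 4.0]))
        assert np.allclose(cdf.probabilities, [1 / 3, 2 / 3, 1.0])

    def test_terminal_probability_is_exactly_one(self, rng):
        cdf = cal.build_cdf(rng.exponential(5.0, 257))
        assert cdf.probabilities[-1] == 1.0
        assert np.all(np.diff(cdf.probabilities) > 0)
        assert np.all(np.diff(cdf.x) >= 0)

    def test_all_zero_input_raises(self):
        with pytest.raises(sq.EmptyCdfError):
            cal.build_cdf(np.zeros(3))

    def test_negatives_removed_for_raw_metric(self):
        cdf = cal.build_cdf(np.array([-5.0, 3.0, -1.0, 9.0]), metric="raw_intensity")
        assert cdf.n == 2

    def test_single_replicate_model_equals_plain_cdf(self, rng):
        values = rng.exponential(3.0, 50)
        a = cal.build_cdf(values)
        b = cal.build_model_cdf([values])
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_pooled_model_cdf_matches_concatenation_oracle(self, rng):
        r1 = rng.exponential(3.0, 40)
        r2 = rng.exponential(3.0, 60)
        model = cal.build_model_cdf([r1, r2])
        pooled = np.sort(np.concatenate([r1, r2]))
        assert np.allclose(model.x, np.log10(pooled))
        assert np.allclose(model.probabilities, np.arange(1, 101) / 100)

    def test_duplicate_values_keep_distinct_probabilities(self):
        cdf = cal.build_cdf(np.array([2.0, 2.0, 2.0]))
        assert np.allclose(cdf.x, np.log10(2.0))
        assert np.allclose(cdf.probabilities, [1 / 3, 2 / 3, 1.0])


class TestCdfPolyFit:
    def _cdf_from_function(self, f, n=200):
        p = np.linspace(0.05, 1.0, n)
        return cal.EmpiricalCdf(x=f(p), probabilities=p)

    def test_exact_quartic_is_interpolated(self):
        quartic = np.polynomial.Polynomial([0.3, -1.2, 2.0, 0.5, -0.7])
        fit = cal.fit_cdf_poly(self._cdf_from_function(quartic))
        assert fit.probabilities.size == 500
        assert fit.probabilities[0] == 0.6 and fit.probabilities[-1] == 0.9
        assert np.allclose(fit.fitted_x, quartic(fit.probabilities), atol=1e-9)

    def test_linear_segment_nested_exactly(self):
        fit = cal.fit_cdf_poly(self._cdf_from_function(lambda p: 3.0 * p - 1.0))
        assert np.allclose(fit.fitted_x, 3.0 * fit.probabilities - 1.0, atol=1e-9)

    def test_too_few_in_range_points_raise(self):
        cdf = cal.EmpiricalCdf(
            x=np.array([0.0, 1.0, 2.0]), probabilities=np.array([0.3, 0.7, 1.0])
        )
        with pytest.raises(sq.CdfFitError):
            cal.fit_cdf_poly(cdf)


class TestSigmaDeltaQcdf:
    def test_self_difference_is_zero(self, rng):
        cdf = cal.build_cdf(rng.exponential(5.0, 1000))
        fit = cal.fit_cdf_poly(cdf)
        assert cal.sigma_delta_qcdf(fit, fit) == 0.0

    def test_constant_shift_sums_to_500_delta(self, rng):
        values = rng.exponential(5.0, 1000)
        delta = 0.37
        fit = cal.fit_cdf_poly(cal.build_cdf(values))
        shifted = cal.fit_cdf_poly(cal.build_cdf(values * 10**delta))
        assert cal.sigma_delta_qcdf(shifted, fit) == pytest.approx(
            500 * delta, rel=1e-9
        )

    def test_mismatched_grids_raise(self, rng):
        fit = cal.fit_cdf_poly(cal.build_cdf(rng.exponential(5.0, 1000)))
        other = cal.fit_cdf_poly(
            cal.build_cdf(rng.exponential(5.0, 1000)), n_points=400
        )
        with pytest.raises(ValueError):
            cal.sigma_delta_qcdf(fit, other)

    def test_sigma_increases_with_concentration(self):
        # higher concentration stochastically dominates in Qi
        cfg = sq.GeneratorConfig(rng_seed=3)
        plate = sq.generate_plate(sq.make_default_design(cfg), cfg)
        curve = sq.cdf_curve(plate)
        ascending = curve.regression_responses[::-1]
        assert np.all(np.diff(ascending) > 0)


class TestCurveMethods:
    def test_plate_of_blanks_only_raises(self):
        cfg = sq.GeneratorConfig(
            raster_lines=3,
            raster_per_line=3,
            concentrations=(100.0,),
            replicate_wells_per_sample=2,
        )
        design = sq.make_default_design(cfg, rows=2, cols=2)
        plate = sq.generate_plate(design, cfg)
        with pytest.raises(sq.RegressionError):
            sq.total_population_curve(plate)

    def test_qi_sample_with_full_population_matches_total(self, small_plate):
        k = next(iter(small_plate.maps.values())).n_spectra
        total = sq.total_population_curve(small_plate)
        qi = sq.qi_sample_curve(small_plate, k=k)
        assert np.allclose(
            qi.replicate_responses, total.replicate_responses, rtol=1e-10
        )
        assert qi.slope == pytest.approx(total.slope, rel=1e-9)

    def test_cdf_requires_blank(self, small_config):
        cfg = sq.GeneratorConfig(
            raster_lines=4,
            raster_per_line=5,
            concentrations=(100.0, 50.0),
            replicate_wells_per_sample=2,
        )
        design = sq.make_default_design(cfg, rows=2, cols=3)
        plate = sq.generate_plate(design, cfg)
        # drop the blank sample from the design
        nonblank_wells = {
            w: i
            for w, i in design.well_to_sample.items()
            if not design.sample(i).is_blank
        }
        stripped = sq.PlateDesign(
            rows=2,
            cols=3,
            samples=tuple(s for s in design.samples if not s.is_blank),
            well_to_sample=nonblank_wells,
            replicate_wells_per_sample=2,
        )
        sub = sq.Plate(
            design=stripped, maps={w: plate.maps[w] for w in nonblank_wells}
        )
        with pytest.raises(ValueError):
            sq.cdf_curve(sub)

    def test_cdf_positive_shift_makes_minimum_zero(self, small_plate):
        curve = sq.cdf_curve(small_plate)
        smallest = min(
            curve.regression_responses.min(), curve.replicate_responses.min()
        )
        assert smallest == pytest.approx(0.0, abs=1e-9)
        assert curve.shift_offset >= 0.0


class TestBlankSubtract:
    def test_blank_minus_itself_is_zero(self, small_plate):
        ref = cal.blank_mean_spectrum(small_plate)
        sub = sq.blank_subtract(small_plate)
        new_ref = cal.blank_mean_spectrum(sub)
        assert np.allclose(new_ref.intensities, 0.0, atol=1e-9)

    def test_total_population_slope_invariant(self, small_plate):
        before = sq.total_population_curve(small_plate)
        after = sq.total_population_curve(sq.blank_subtract(small_plate))
        assert after.slope == pytest.approx(before.slope, rel=1e-9)
        assert after.r_squared == pytest.approx(before.r_squared, rel=1e-6)
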