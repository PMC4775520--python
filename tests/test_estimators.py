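"""Per-assemblage spectrum estimators: hand-worked examples and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sizespectra as sz
from sizespectra.core import BinnedSpectrum

masses_lists = st.lists(
    st.floats(min_value=0.01, max_value=1e7, allow_nan=False,
              allow_infinity=False),
    min_size=1, max_size=60)


class TestClassAssign:
    @pytest.mark.parametrize("masses, scheme, expected", [
        ([8.0], "lower", [3]),                      # exact power of two
        ([1.5, 3.0, 3.0, 6.0], "lower", [0, 1, 1, 2]),
        ([1.5, 3.0, 3.0, 6.0], "upper", [1, 2, 2, 3]),
        ([1.5, 3.0, 3.0, 6.0], "half", [1, 2, 2, 3]),
    ])
    def test_hand_examples(self, masses, scheme, expected):
        assert list(sz.log2_class_assign(masses, scheme)) == expected

    def test_upper_shifts_one_step_above_lower(self):
        # for masses off the class boundaries the upper-rounding class
        # label is exactly one above the lower-rounding one
        masses = [1.5, 3.0, 3.0, 6.0]
        lower = sz.log2_class_assign(masses, "lower")
        upper = sz.log2_class_assign(masses, "upper")
        assert list(upper - lower) == [1, 1, 1, 1]

    def test_non_positive_mass_rejected(self):
        with pytest.raises(sz.SizeSpectraError):
            sz.log2_class_assign([4.0, 0.0], "lower")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(sz.ConfigurationError):
            sz.log2_class_assign([4.0], "nearest")


class TestBinSpectrum:
    def test_single_species_density(self):
        spec = sz.bin_spectrum([3.0], "lower")
        assert spec.n_classes == 1
        assert spec.count[0] == 1
        assert spec.linear_width_g[0] == 2.0
        assert spec.density[0] == 0.5

    def test_midpoints_are_arithmetic_means_of_edges(self):
        spec = sz.bin_spectrum([3.0, 6.0], "lower")
        assert list(spec.midpoint_g) == [3.0, 6.0]

    def test_width_correction_divides_counts(self):
        # 4, 2, 1 species in [2,4), [4,8), [8,16): densities 2, 0.5, 0.125
        masses = [2.1, 2.5, 3.0, 3.9, 5.0, 6.0, 9.0]
        spec = sz.bin_spectrum(masses, "lower")
        assert list(spec.count) == [4, 2, 1]
        assert list(spec.density) == [2.0, 0.5, 0.125]

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(masses=masses_lists, scheme=st.sampled_from(sz.SCHEMES))
    def test_counts_conserve_richness(self, masses, scheme):
        spec = sz.bin_spectrum(masses, scheme)
        assert spec.richness == len(masses)
        assert np.all(np.diff(spec.class_index) > 0)
        assert np.allclose(spec.density * spec.linear_width_g, spec.count)


def _spectrum(midpoints, densities):
    mid = np.asarray(midpoints, float)
    dens = np.asarray(densities, float)
    width = np.ones_like(mid)
    return BinnedSpectrum(scheme="lower", class_index=np.arange(mid.size),
                          lower_edge_g=mid - 0.5, upper_edge_g=mid + 0.5,
                          linear_width_g=width, midpoint_g=mid,
                          count=dens * width, density=dens)


class TestLogLogFit:
    def test_reciprocal_density_gives_slope_minus_one(self):
        slope, _, r2 = sz.fit_loglog_slope(
            _spectrum([2.0, 4.0, 8.0, 16.0], [8.0, 4.0, 2.0, 1.0]))
        assert slope == pytest.approx(-1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_density_gives_zero_slope(self):
        slope, _, _ = sz.fit_loglog_slope(
            _spectrum([3.0, 6.0, 12.0], [0.7, 0.7, 0.7]))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_quartering_density_per_doubling_gives_slope_minus_two(self):
        slope, _, r2 = sz.fit_loglog_slope(
            _spectrum([3.0, 6.0, 12.0], [2.0, 0.5, 0.125]))
        assert slope == pytest.approx(-2.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_slope_is_log_base_invariant(self):
        spec = sz.bin_spectrum(sz.generate_fractal_pool(
            500, 2.0, 2.0 ** 16, -0.8, 0), "half")
        slope, _, _ = sz.fit_loglog_slope(spec)
        for log in (np.log, np.log2):
            alt = stats.linregress(log(spec.midpoint_g),
                                   log(spec.density)).slope
            assert alt == pytest.approx(slope, abs=1e-12)

    def test_two_occupied_classes_is_an_error(self):
        with pytest.raises(sz.InsufficientBinsError):
            sz.estimate_slope([3.0, 3.5, 5.0, 6.0])  # only 2 classes

    def test_estimate_is_mean_of_scheme_fits(self):
        est = sz.estimate_slope(sz.generate_fractal_pool(
            2000, 2.0, 2.0 ** 18, -1.0 / 3.0, 5))
        assert est.slope == pytest.approx(
            np.mean([f.slope for f in est.fits]), abs=1e-14)
        assert {f.scheme for f in est.fits} == set(sz.SCHEMES)


class TestSkewness:
    def test_symmetric_sample_is_unskewed(self):
        assert sz.g1_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0,
                                                                abs=1e-12)

    def test_hand_worked_value(self):
        # deviations (-1,-1,-1,3): sum d^3 = 24, s = 2, g1 = 4*24/(3*2*8)
        assert sz.g1_skewness([1, 1, 1, 5]) == pytest.approx(2.0, abs=1e-12)

    def test_geometric_progression_symmetric_in_logs(self):
        values = [1.0, 4.0, 16.0]
        assert sz.g1_skewness(np.log2(values)) == pytest.approx(0.0,
                                                                abs=1e-12)
        assert sz.g1_skewness(values) > 0

    @pytest.mark.parametrize("values", [[1.0, 2.0], [3.0, 3.0, 3.0]])
    def test_undefined_cases(self, values):
        with pytest.raises(sz.UndefinedSkewnessError):
            sz.g1_skewness(values)


class TestHalfSampleMode:
    @pytest.mark.parametrize("values, expected", [
        ([5.0, 5.0, 5.0], 5.0),
        ([0.0, 1.0, 1.1, 9.0], 1.05),   # tightest half is {1, 1.1}
        ([7.0], 7.0),
        ([2.0, 6.0], 4.0),
    ])
    def test_hand_examples(self, values, expected):
        assert sz.half_sample_mode(values) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(sz.SizeSpectraError):
            sz.half_sample_mode([])

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(values=st.lists(st.floats(min_value=0.25, max_value=4096.0,
                                     allow_nan=False), min_size=1,
                           max_size=40),
           c=st.sampled_from([0.25, 0.5, 2.0, 8.0, 1024.0]))
    def test_scale_equivariance(self, values, c):
        # powers of two scale floats exactly, so window choices agree
        x = np.asarray(values)
        assert sz.half_sample_mode(c * x) == pytest.approx(
            c * sz.half_sample_mode(x), rel=1e-12)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(values=st.lists(st.integers(min_value=-1000, max_value=1000),
                           min_size=1, max_size=40),
           t=st.integers(min_value=-50, max_value=50))
    def test_translation_equivariance(self, values, t):
        x = np.asarray(values, float)
        assert sz.half_sample_mode(x + t) == pytest.approx(
            sz.half_sample_mode(x) + t, abs=1e-9)

    def test_log_mode_shifts_above_linear_mode_on_skewed_masses(self):
        # on a right-skewed mass sample the mass-scale mode sits in the
        # dense small-bodied region while the log-scale mode lands near
        # the geometric centre, well above it
        rng = np.random.default_rng(0)
        masses = rng.lognormal(np.log(100), 1.5, 200)
        linear = sz.half_sample_mode(masses)
        log2 = 2.0 ** sz.half_sample_mode(np.log2(masses))
        assert log2 > 2.0 * linear


class TestConversions:
    @pytest.mark.parametrize("slope, expected", [
        (-1.0, 100.0), (0.0, 0.0),
    ])
    def test_halving_gain_exact_points(self, slope, expected):
        assert sz.fractal_expected_increase(slope) == pytest.approx(expected)

    def test_positive_slope_rejected(self):
        with pytest.raises(sz.ConfigurationError):
            sz.fractal_expected_increase(0.5)

    @pytest.mark.parametrize("slope_mass, expected", [
        (-2.0 / 3.0, -2.0), (0.0, 0.0), (-1.26, -3.78),
    ])
    def test_length_axis_conversion(self, slope_mass, expected):
        assert sz.mass_slope_to_length_slope(slope_mass) == pytest.approx(
            expected)


class TestShapeSummary:
    def test_direct_count_and_median(self):
        sample = sz.MassSample([50.0, 50.0, 200.0, 200.0], "L", "local")
        summary = sz.shape_summary(sample)
        assert summary.pct_under_100g == 50.0
        assert summary.median_g == 125.0
        assert summary.richness == 4

    def test_identical_masses_degrade_gracefully(self):
        sample = sz.MassSample([64.0] * 6, "L", "local")
        summary = sz.shape_summary(sample)
        assert summary.skew_linear is None
        assert "skew_linear" in summary.errors
        assert "slope" in summary.errors          # single size class
        assert summary.mode_linear_g == 64.0
        assert summary.pct_under_100g == 100.0

    def test_mode_and_median_inside_sample_range(self, turnover_pool):
        summary = sz.shape_summary(turnover_pool.mass_sample())
        lo, hi = turnover_pool.masses_g.min(), turnover_pool.masses_g.max()
        for value in (summary.mode_linear_g, summary.mode_log2_g,
                      summary.median_g):
            assert lo <= value <= hi

    def test_log_transform_reduces_right_skew(self, turnover_pool):
        """Log2 transformation symmetrizes right-skewed mass data, so
        log2 skewness falls below linear skewness on every assemblage."""
        at = sz.sample_localities(turnover_pool, 4)
        summaries = sz.summarize_assemblages(at, pools=[turnover_pool])
        defined = summaries.dropna(subset=["skew_linear", "skew_log2"])
        assert len(defined) == len(summaries)
        assert (defined["skew_log2"] < defined["skew_linear"]).all()

    def test_continental_small_fraction_exceeds_local_mean(
            self, turnover_pool):
        at = sz.sample_localities(turnover_pool, 4)
        summaries = sz.summarize_assemblages(at, pools=[turnover_pool])
        cont = summaries[summaries["scale"] == "continental"]
        loc = summaries[summaries["scale"] == "local"]
        assert cont["pct_under_100g"].iloc[0] > loc["pct_under_100g"].mean()
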