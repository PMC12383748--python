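"""Information markers: entropy, variance curve, 1-AUC, PC95, power law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imginfo import (
    VarianceCurve,
    cumulative_variance,
    fit_inverse_power_law,
    info_report,
    inverse_auc,
    loglaw_metric,
    pc95,
    shannon_entropy,
    standardize,
)
from imginfo.metrics import MetricValidationError, PowerLawFit

from conftest import (
    brute_force_cumulative_variance,
    data_with_sample_covariance,
    make_feature_matrix,
)


def curve_from(y, n_samples=100):
    y = np.asarray(y, dtype=float)
    return VarianceCurve(y=y, d=y.size, n_samples=n_samples)


class TestStandardize:
    def test_zscore_and_idempotence(self, rng):
        fm = make_feature_matrix(rng.normal(5, 3, size=(30, 4)))
        z = standardize(fm)
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-12)
        z2 = standardize(z)
        np.testing.assert_allclose(z2.values, z.values, atol=1e-12)

    def test_constant_column_dropped_and_recorded(self, rng):
        vals = rng.normal(size=(20, 3))
        vals[:, 1] = 4.2
        z = standardize(make_feature_matrix(vals, names=("a", "const", "b")))
        assert z.feature_names == ("a", "b")
        assert z.provenance["dropped_constant_columns"] == ["const"]

    def test_all_constant_rejected(self):
        with pytest.raises(MetricValidationError, match="constant"):
            standardize(make_feature_matrix(np.ones((10, 3))))


class TestCumulativeVariance:
    def test_constructed_diagonal_spectrum(self):
        fm = data_with_sample_covariance([4, 3, 2, 1], n_rows=50)
        curve = cumulative_variance(fm)
        np.testing.assert_allclose(curve.y, [0.4, 0.7, 0.9, 1.0], atol=1e-10)

    def test_rank_one_data(self, rng):
        col = rng.normal(size=(40, 1))
        fm = make_feature_matrix(np.hstack([col, 3.0 * col, -0.5 * col]))
        curve = cumulative_variance(fm)
        np.testing.assert_allclose(curve.y, 1.0, atol=1e-12)

    def test_matches_brute_force_eigendecomposition(self, rng):
        X = rng.normal(size=(200, 50))
        curve = cumulative_variance(make_feature_matrix(X))
        np.testing.assert_allclose(
            curve.y, brute_force_cumulative_variance(X), atol=1e-8
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(5, 60), p=st.integers(2, 40))
    def test_curve_is_nondecreasing_and_ends_at_one(self, seed, n, p):
        X = np.random.default_rng(seed).normal(size=(n, p))
        curve = cumulative_variance(make_feature_matrix(X))
        assert curve.d == min(n - 1, p)
        assert np.all(np.diff(curve.y) >= -1e-12)
        assert curve.y[-1] == pytest.approx(1.0, abs=1e-9)


class TestPC95:
    def test_diagonal_spectrum_needs_all_components(self):
        assert pc95(curve_from([0.4, 0.7, 0.9, 1.0])) == 4

    def test_rank_one_crosses_immediately(self):
        assert pc95(curve_from([1.0, 1.0, 1.0])) == 1

    def test_isotropic_twenty(self):
        assert pc95(curve_from(np.arange(1, 21) / 20)) == 19

    def test_threshold_configurable(self):
        assert pc95(curve_from([0.4, 0.7, 0.9, 1.0]), threshold=0.65) == 2


class TestInverseAUC:
    def test_rank_one_is_zero(self):
        assert inverse_auc(curve_from([1.0, 1.0, 1.0, 1.0])) == pytest.approx(0.0)

    @pytest.mark.parametrize("d", [2, 5, 10, 50])
    def test_isotropic_closed_form(self, d):
        # brute-force trapezoid of y=k/d over x=(k-1)/(d-1) gives (d-1)/(2d)
        assert inverse_auc(curve_from(np.arange(1, d + 1) / d)) == pytest.approx(
            (d - 1) / (2 * d), abs=1e-12
        )

    def test_hand_trapezoid(self):
        # panels: (0.55 + 0.8 + 0.95)/3 of area -> 1 - 2.3/3
        assert inverse_auc(curve_from([0.4, 0.7, 0.9, 1.0])) == pytest.approx(
            1 - 2.3 / 3, abs=1e-12
        )

    def test_single_point_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert inverse_auc(curve_from([1.0])) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), d=st.integers(2, 50))
    def test_bounds_over_random_spectra(self, seed, d):
        lam = np.sort(np.random.default_rng(seed).uniform(0.01, 1, size=d))[::-1]
        y = np.cumsum(lam) / lam.sum()
        y[-1] = 1.0
        v = inverse_auc(curve_from(y))
        assert 0.0 <= v <= (d - 1) / (2 * d) + 1e-12


class TestPowerLawFit:
    def test_noiseless_recovery(self):
        n = np.arange(1, 101)
        y = -0.8 * n**-0.7 + 1.0
        fit = fit_inverse_power_law(y)
        assert fit.converged
        assert fit.a == pytest.approx(-0.8, abs=1e-3)
        assert fit.b == pytest.approx(0.7, abs=1e-3)
        assert fit.c == pytest.approx(1.0, abs=1e-3)
        assert fit.rss <= 1e-10
        assert fit.r2 >= 1 - 1e-9

    def test_prediction_at_one_is_a_plus_c(self):
        fit = PowerLawFit(a=-0.6, b=0.9, c=0.98, rss=0, r2=1, converged=True, n_points=10)
        assert fit.predict(1.0) == pytest.approx(-0.6 + 0.98)

    def test_determinism(self, rng):
        y = np.clip(-0.5 * np.arange(1.0, 51.0) ** -0.4 + 0.95, 0, 1)
        f1, f2 = fit_inverse_power_law(y), fit_inverse_power_law(y)
        assert (f1.a, f1.b, f1.c, f1.rss) == (f2.a, f2.b, f2.c, f2.rss)

    def test_too_few_points_rejected(self):
        with pytest.raises(MetricValidationError, match=">= 4"):
            fit_inverse_power_law(np.array([0.5, 0.8, 1.0]))


class TestLogLawMetric:
    def test_default_formula(self):
        fit = PowerLawFit(a=-0.5, b=0.3, c=1, rss=0, r2=1, converged=True, n_points=10)
        assert loglaw_metric(fit) == pytest.approx(math.log10(0.5) - 0.3, abs=1e-12)

    def test_unit_a_zero_b(self):
        fit = PowerLawFit(a=1.0, b=0.0, c=1, rss=0, r2=1, converged=True, n_points=10)
        assert loglaw_metric(fit) == 0.0

    def test_monotone_decreasing_in_decay_rate(self):
        vals = [
            loglaw_metric(
                PowerLawFit(a=-0.5, b=b, c=1, rss=0, r2=1, converged=True, n_points=10)
            )
            for b in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_zero_a_rejected(self):
        fit = PowerLawFit(a=0.0, b=0.3, c=1, rss=0, r2=1, converged=True, n_points=10)
        with pytest.raises(MetricValidationError):
            loglaw_metric(fit)

    def test_inverse_variants(self):
        fit = PowerLawFit(a=-0.5, b=0.25, c=1, rss=0, r2=1, converged=True, n_points=10)
        assert loglaw_metric(fit, "inverse_a") == -2.0
        assert loglaw_metric(fit, "inverse_b") == 4.0


class TestShannonEntropy:
    def test_constant_matrix_is_zero(self):
        assert shannon_entropy(make_feature_matrix(np.full((10, 3), 2.0))) == 0.0

    def test_two_bins_equal_mass(self):
        vals = np.array([0.0, 1.0] * 50).reshape(-1, 1)
        assert shannon_entropy(make_feature_matrix(vals)) == pytest.approx(0.125)

    def test_equal_mass_per_bin_is_one(self):
        vals = np.arange(256.0).reshape(-1, 1)
        assert shannon_entropy(make_feature_matrix(vals)) == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_monotone_affine_invariance_per_feature(self, seed):
        # bin edges track each column's min-max, so any strictly monotone
        # affine map (including decreasing) leaves the default marker unchanged
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 4))
        scales = rng.choice([-1, 1], size=4) * rng.uniform(0.5, 20, size=4)
        offsets = rng.uniform(-100, 100, size=4)
        a = shannon_entropy(make_feature_matrix(X), method="per_feature")
        b = shannon_entropy(
            make_feature_matrix(X * scales + offsets), method="per_feature"
        )
        assert a == pytest.approx(b, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_increasing_affine_invariance_pooled(self, seed):
        # pooled mixing is only symmetric under increasing maps: reversing one
        # column rearranges the pooled histogram
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 4))
        scales = rng.uniform(0.5, 20, size=4)
        offsets = rng.uniform(-100, 100, size=4)
        a = shannon_entropy(make_feature_matrix(X), method="pooled")
        b = shannon_entropy(make_feature_matrix(X * scales + offsets), method="pooled")
        assert a == pytest.approx(b, abs=1e-12)

    def test_pooled_mixture_can_exceed_both_parts(self):
        # two features concentrated in different bins: pooled entropy beats each
        left = np.repeat([0.0, 0.1], 50).reshape(-1, 1)
        right = np.repeat([0.9, 1.0], 50).reshape(-1, 1)
        both = np.hstack([left, right])
        e_left = shannon_entropy(make_feature_matrix(left), method="pooled")
        e_both = shannon_entropy(make_feature_matrix(both), method="pooled")
        assert e_both >= e_left  # 0.25 vs 0.125: distinct normalised supports add up

    def test_empty_matrix_rejected(self):
        with pytest.raises((MetricValidationError, ValueError)):
            shannon_entropy(make_feature_matrix(np.empty((1, 0))))


class TestInfoReport:
    def test_composition_without_standardization(self):
        fm = data_with_sample_covariance([4, 3, 2, 1], n_rows=50)
        rep = info_report(fm, standardize_features=False)
        assert rep.pc95 == 4
        assert rep.auc1 == pytest.approx(1 - 2.3 / 3, abs=1e-9)

    def test_determinism(self, rng):
        fm = make_feature_matrix(rng.normal(size=(40, 8)))
        assert info_report(fm).to_json() == info_report(fm).to_json()

    def test_rank_one_matrix_degenerate_markers(self, rng):
        col = rng.normal(size=(30, 1))
        fm = make_feature_matrix(np.hstack([col, 2 * col, -col, 0.1 * col]))
        rep = info_report(fm)
        assert rep.pc95 == 1
        assert rep.auc1 == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_row_permutation_changes_no_marker(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 6))
        rep1 = info_report(make_feature_matrix(X))
        rep2 = info_report(make_feature_matrix(X[rng.permutation(30)]))
        assert rep1.entropy == pytest.approx(rep2.entropy, abs=1e-12)
        assert rep1.auc1 == pytest.approx(rep2.auc1, abs=1e-9)
        assert rep1.pc95 == rep2.pc95
        assert rep1.loglaw == pytest.approx(rep2.loglaw, abs=1e-6)
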