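"""Closed-form distribution: functions, moments, entropy, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from hltexpd.distribution import HalfLogisticTruncExp, HLTexpdParams

PARAM_SETTINGS = [(0.0, 1.0), (2.0, 0.5), (17.88, 0.026)]


def eta_series_moment(p: int) -> float:
    """Independent oracle: standard half-logistic raw moment 2*p!*eta(p)."""
    eta = np.log(2.0) if p == 1 else (1 - 2 ** (1 - p)) * special.zeta(p)
    return 2.0 * special.factorial(p) * eta


class TestParams:
    @pytest.mark.parametrize("a, theta", [(0.0, -1.0), (0.0, 0.0), (np.inf, 1.0)])
    def test_invalid(self, a, theta):
        with pytest.raises(ValueError):
            HLTexpdParams(a, theta)


class TestPointFunctions:
    @pytest.mark.parametrize(
        "a, theta, x, expected",
        [
            (0.0, 1.0, 0.0, 0.5),              # 2/(1+1)^2
            (0.0, 1.0, np.log(3), 0.375),      # e^{-x} = 1/3
            (2.0, 1.0, 1.0, 0.0),              # below threshold
        ],
    )
    def test_pdf(self, a, theta, x, expected):
        assert HalfLogisticTruncExp(a, theta).pdf(x) == pytest.approx(expected, abs=1e-14)

    @pytest.mark.parametrize(
        "a, theta, x, expected",
        [
            (0.0, 1.0, 0.0, 0.0),
            (0.0, 1.0, np.log(3), 0.5),        # the median
            (0.025, 0.735, 1e9, 1.0),
        ],
    )
    def test_cdf(self, a, theta, x, expected):
        assert HalfLogisticTruncExp(a, theta).cdf(x) == pytest.approx(expected, abs=1e-12)

    def test_survival_complements_cdf(self):
        d = HalfLogisticTruncExp(0.0, 1.0)
        for x in [0.0, np.log(3), 5.0, -5.0]:
            assert d.sf(x) + d.cdf(x) == pytest.approx(1.0, abs=1e-15)
        assert d.sf(-5.0) == 1.0

    def test_matches_scipy_halflogistic(self):
        # independent route: the law is a shifted half-logistic
        a, theta = 0.08, 0.869
        mine = HalfLogisticTruncExp(a, theta)
        ref = stats.halflogistic(loc=a, scale=1.0 / theta)
        x = np.linspace(a, a + 10 / theta, 101)
        np.testing.assert_allclose(mine.pdf(x), ref.pdf(x), atol=1e-12)
        np.testing.assert_allclose(mine.cdf(x), ref.cdf(x), atol=1e-12)

    def test_extreme_tail_no_overflow(self):
        d = HalfLogisticTruncExp(0.0, 2.0)
        assert d.sf(1000.0) == 0.0 or d.sf(1000.0) >= 0.0
        assert np.isfinite(d.logpdf(400.0))


class TestHazard:
    def test_endpoints(self):
        d = HalfLogisticTruncExp(0.0, 1.0)
        assert d.hazard(0.0) == pytest.approx(0.5)
        assert d.hazard(1e4) == pytest.approx(1.0, abs=1e-12)

    def test_equals_pdf_over_survival(self):
        d = HalfLogisticTruncExp(0.08, 0.869)
        t = np.linspace(0.08, 12.0, 200)
        np.testing.assert_allclose(d.hazard(t), d.pdf(t) / d.sf(t), atol=1e-12)

    def test_increasing_and_bounded(self):
        d = HalfLogisticTruncExp(1.0, 0.4)
        t = np.linspace(1.0, 40.0, 500)
        h = d.hazard(t)
        assert np.all(np.diff(h) > 0)
        assert np.all(h >= 0.2) and np.all(h < 0.4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            HalfLogisticTruncExp(1.0, 1.0).hazard(0.5)


class TestQuantile:
    def test_zero_maps_to_threshold(self):
        assert HalfLogisticTruncExp(3.5, 0.7).ppf(0.0) == 3.5

    @pytest.mark.parametrize("a, theta", [(0.0, 1.0), (17.88, 0.026)])
    def test_median_against_bisection_oracle(self, a, theta):
        from scipy.optimize import bisect

        d = HalfLogisticTruncExp(a, theta)
        root = bisect(lambda x: d.cdf(x) - 0.5, a, a + 50 / theta, xtol=1e-12)
        assert d.ppf(0.5) == pytest.approx(root, abs=1e-9)
        assert d.ppf(0.5) == pytest.approx(a + np.log(3) / theta, rel=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            HalfLogisticTruncExp().ppf(-0.1)
        assert HalfLogisticTruncExp().ppf(1.0) == np.inf

    @settings(max_examples=60, derandomize=True)
    @given(
        p=st.floats(min_value=0.001, max_value=0.999),
        a=st.floats(min_value=-5, max_value=20),
        theta=st.floats(min_value=0.01, max_value=10),
    )
    def test_cdf_inverts_quantile(self, p, a, theta):
        d = HalfLogisticTruncExp(a, theta)
        assert d.cdf(d.ppf(p)) == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("a, theta", PARAM_SETTINGS + [(0.5, 3.0), (-1.0, 0.2)])
    def test_inversion_grid(self, a, theta):
        d = HalfLogisticTruncExp(a, theta)
        p = np.concatenate([[0.001, 0.01], np.arange(0.1, 1.0, 0.1), [0.99, 0.999]])
        np.testing.assert_allclose(d.cdf(d.ppf(p)), p, atol=1e-10)


class TestMoments:
    @pytest.mark.parametrize("p", [1, 2, 3, 4])
    def test_standard_moments_match_series_oracle(self, p):
        d = HalfLogisticTruncExp(0.0, 1.0)
        expected = eta_series_moment(p)
        assert d.raw_moment(p, method="closed") == pytest.approx(expected, rel=1e-12)
        assert d.raw_moment(p, method="quadrature") == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("a, theta", PARAM_SETTINGS)
    @pytest.mark.parametrize("p", [1, 2, 3, 4])
    def test_closed_form_matches_quadrature(self, a, theta, p):
        d = HalfLogisticTruncExp(a, theta)
        assert d.raw_moment(p, "closed") == pytest.approx(d.raw_moment(p, "quadrature"), rel=1e-8)

    def test_first_moments_printed_forms(self):
        d = HalfLogisticTruncExp(0.0, 1.0)
        assert d.raw_moment(1) == pytest.approx(np.log(4), rel=1e-12)
        assert d.raw_moment(2) == pytest.approx(np.pi**2 / 3, rel=1e-12)
        assert d.raw_moment(3) == pytest.approx(9 * special.zeta(3), rel=1e-12)

    def test_variance_constant(self):
        # var = (pi^2 - 3 log^2 4)/(3 theta^2) ~= 1.368/theta^2
        for theta in (1.0, 0.5):
            d = HalfLogisticTruncExp(0.0, theta)
            assert d.var() * theta**2 == pytest.approx(1.36805, rel=1e-4)
            assert d.var() * theta**2 == pytest.approx((np.pi**2 - 3 * np.log(4) ** 2) / 3, rel=1e-12)
            assert d.var() == pytest.approx(d.moment_set().variance, rel=1e-10)

    def test_third_central_moment(self):
        # published value 2.464 is truncated from 2.46473
        assert HalfLogisticTruncExp(0.0, 1.0).moment_set().mu3 == pytest.approx(2.464, abs=1e-3)

    def test_shape_constants_location_scale_invariant(self):
        m1 = HalfLogisticTruncExp(0.0, 1.0).moment_set()
        m2 = HalfLogisticTruncExp(7.0, 0.3).moment_set()
        assert m1.skewness == pytest.approx(m2.skewness, abs=1e-9)
        assert m1.kurtosis == pytest.approx(m2.kurtosis, abs=1e-9)
        assert m1.skewness == pytest.approx(1.54, abs=5e-3)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            HalfLogisticTruncExp().raw_moment(0)
        with pytest.raises(ValueError):
            HalfLogisticTruncExp().raw_moment(1.5)


class TestEntropy:
    @pytest.mark.parametrize("a, theta", [(0.0, 1.0), (3.0, 1.0), (0.0, np.exp(2))])
    def test_matches_numeric_integral(self, a, theta):
        d = HalfLogisticTruncExp(a, theta)
        val, _ = integrate.quad(
            lambda x: -d.pdf(x) * d.logpdf(x), a, d.ppf(1 - 1e-13), limit=200
        )
        assert d.entropy() == pytest.approx(val, abs=1e-6)

    def test_known_values(self):
        assert HalfLogisticTruncExp(0.0, 1.0).entropy() == pytest.approx(2 - np.log(2), rel=1e-12)
        assert HalfLogisticTruncExp(0.0, np.exp(2)).entropy() == pytest.approx(-np.log(2), abs=1e-12)

    def test_scale_property(self):
        for theta in (0.3, 1.7):
            e1 = HalfLogisticTruncExp(0.0, theta).entropy()
            e2 = HalfLogisticTruncExp(5.0, 2 * theta).entropy()
            assert e1 - e2 == pytest.approx(np.log(2), rel=1e-12)


class TestSampling:
    def test_reproducible(self):
        d = HalfLogisticTruncExp(0.0, 1.0)
        assert d.rvs(1, random_state=42) == d.rvs(1, random_state=42)

    def test_support_and_mean(self):
        d = HalfLogisticTruncExp(5.0, 2.0)
        x = d.rvs(10000, random_state=7)
        assert x.min() > 5.0
        target = 5.0 + np.log(4) / 2.0
        assert abs(x.mean() - target) < 3 * d.std() / np.sqrt(10000)

    def test_kolmogorov_distance(self):
        d = HalfLogisticTruncExp(0.0, 1.0)
        x = d.rvs(100_000, random_state=3)
        ks = stats.kstest(x, d.cdf).statistic
        assert ks < 0.01

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            HalfLogisticTruncExp().rvs(0)
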