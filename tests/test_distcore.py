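"""Distribution-function correctness against independent oracles.

The pdf/cdf are checked against scipy's exponentially-modified normal
(`exponnorm`), against direct numeric convolution of the Gaussian and
exponential components, and against quadrature of the pdf itself.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import exponnorm

from exgtools import (
    BracketError,
    ExGParams,
    ExGStats,
    SkewnessRangeError,
    exg_cdf,
    exg_lamb_cdf,
    exg_lamb_pdf,
    exg_log_pdf,
    exg_pdf,
    exg_quantile,
    find_zero,
    gauss_cdf,
    gauss_pdf,
    integrate,
    pars_to_stats,
    stats_to_pars,
)

from conftest import lamb_grid_params


def scipy_dist(p):
    return exponnorm(p.tau / p.sigma, loc=p.mu, scale=p.sigma)


class TestGaussian:
    def test_mode_values(self):
        assert gauss_pdf(0.0, 0.0, 1.0) == pytest.approx(1 / math.sqrt(2 * math.pi))
        assert gauss_pdf(5.0, 5.0, 2.0) == pytest.approx(1 / (2 * math.sqrt(2 * math.pi)))

    def test_pdf_normalizes_by_quadrature(self):
        total = integrate(lambda t: gauss_pdf(t, 3.0, 2.0), 3 - 16, 3 + 16, order=64)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_cdf_symmetry_and_coverage(self):
        assert gauss_cdf(7.0, 7.0, 3.0) == pytest.approx(0.5)
        cover = gauss_cdf(1.0, 0.0, 1.0) - gauss_cdf(-1.0, 0.0, 1.0)
        assert cover == pytest.approx(0.6826895, abs=1e-6)

    def test_cdf_matches_pdf_quadrature(self):
        expected = integrate(lambda t: gauss_pdf(t, 0.0, 1.0), -12.0, 2.0, order=64)
        assert gauss_cdf(2.0, 0.0, 1.0) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("bad_sigma", [0.0, -1.0])
    def test_rejects_nonpositive_sigma(self, bad_sigma):
        with pytest.raises(ValueError):
            gauss_pdf(0.0, 0.0, bad_sigma)
        with pytest.raises(ValueError):
            gauss_cdf(0.0, 0.0, bad_sigma)


class TestExGaussianDensity:
    def test_matches_component_convolution(self):
        # f(x) = int g(u; mu, sigma) * h(x - u; tau) du over u <= x
        p = ExGParams(0.0, 1.0, 1.0)

        def conv(x):
            val, _ = quad(
                lambda u: gauss_pdf(u, p.mu, p.sigma)
                * math.exp(-(x - u) / p.tau) / p.tau,
                x - 60.0,
                x,
                limit=200,
            )
            return val

        for x in (-2.0, 0.0, 1.0, 4.0):
            assert exg_pdf(x, p) == pytest.approx(conv(x), abs=1e-9)

    @pytest.mark.parametrize(
        "params",
        [ExGParams(0, 1, 1), ExGParams(500, 50, 150), ExGParams(451.09, 47.33, 146.81)],
        ids=["unit", "rt-scale", "young_gng"],
    )
    def test_matches_scipy_exponnorm(self, params):
        d = scipy_dist(params)
        st_ = pars_to_stats(params)
        xs = st_.M + st_.S * np.linspace(-4, 8, 25)
        np.testing.assert_allclose(exg_pdf(xs, params), d.pdf(xs), rtol=1e-12)
        np.testing.assert_allclose(exg_cdf(xs, params), d.cdf(xs), rtol=1e-10, atol=1e-14)

    def test_far_left_tail_vanishes_without_overflow(self):
        v = exg_pdf(-50.0, ExGParams(0, 1, 1))
        assert np.isfinite(v) and 0.0 <= v < 1e-100

    def test_normalizes_across_asymmetries(self):
        for p in lamb_grid_params([0.05, 0.2, 0.5, 0.8, 0.95]):
            st_ = pars_to_stats(p)
            total = integrate(
                lambda t: exg_pdf(t, p), st_.M - 12 * st_.S, st_.M + 40 * st_.S,
                order=64, panels=32,
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_moment_identities_by_quadrature(self):
        # mean, variance and skewness recovered by integrating the density
        for p in lamb_grid_params([0.2, 0.5, 0.8]):
            st_ = pars_to_stats(p)
            a, b = st_.M - 12 * st_.S, st_.M + 40 * st_.S
            m = integrate(lambda t: t * exg_pdf(t, p), a, b, order=64, panels=32)
            v = integrate(lambda t: (t - st_.M) ** 2 * exg_pdf(t, p), a, b, order=64, panels=32)
            k = integrate(
                lambda t: ((t - st_.M) / st_.S) ** 3 * exg_pdf(t, p), a, b,
                order=64, panels=32,
            )
            assert m == pytest.approx(st_.M, rel=1e-6)
            assert v == pytest.approx(st_.S**2, rel=1e-6)
            assert k == pytest.approx(st_.K, rel=1e-6)

    def test_cdf_derivative_is_pdf(self, true_params):
        st_ = pars_to_stats(true_params)
        xs = st_.M + st_.S * np.linspace(-2.5, 5, 20)
        h = 1e-4 * st_.S
        fd = (exg_cdf(xs + h, true_params) - exg_cdf(xs - h, true_params)) / (2 * h)
        np.testing.assert_allclose(fd, exg_pdf(xs, true_params), rtol=1e-6)

    def test_cdf_limits(self, true_params):
        assert exg_cdf(-1e6, true_params) == 0.0
        assert exg_cdf(1e7, true_params) == 1.0

    def test_cdf_worked_tail_point(self, young_gng):
        # 0.1% of the distribution lies beyond 1472.84 ms
        assert exg_cdf(1472.84, young_gng) == pytest.approx(0.999, abs=1e-4)

    def test_cdf_matches_pdf_quadrature(self):
        p = ExGParams(0, 1, 1)
        expected = integrate(lambda t: exg_pdf(t, p), -40.0, 1.0, order=64, panels=32)
        assert exg_cdf(1.0, p) == pytest.approx(expected, abs=1e-8)


class TestLogPdf:
    def test_consistent_with_pdf(self):
        p = ExGParams(0, 1, 1)
        assert math.exp(exg_log_pdf(0.0, p)) == pytest.approx(exg_pdf(0.0, p), abs=1e-12)

    def test_far_tail_matches_convolution_in_log_space(self):
        # at x = -50 the naive exp*erfc product underflows; the log form
        # must still match scipy's stable log-density
        p = ExGParams(0, 1, 1)
        assert exg_log_pdf(-50.0, p) == pytest.approx(scipy_dist(p).logpdf(-50.0), rel=1e-10)

    def test_finite_over_huge_range(self):
        p = ExGParams(500, 50, 150)
        xs = np.linspace(-1e4, 1e5, 500)
        assert np.all(np.isfinite(exg_log_pdf(xs, p)))


class TestLambdaForm:
    def test_is_substitution_into_canonical_form(self):
        p = ExGParams(-0.5, math.sqrt(0.75), 0.5)
        for z in (-2.0, 0.0, 2.0):
            assert exg_lamb_pdf(z, 0.5) == pytest.approx(exg_pdf(z, p), abs=1e-12)
            assert exg_lamb_cdf(z, 0.5) == pytest.approx(exg_cdf(z, p), abs=1e-12)

    @pytest.mark.parametrize("lamb", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_standardized_moments(self, lamb):
        m = integrate(lambda z: z * exg_lamb_pdf(z, lamb), -12, 40, order=64, panels=32)
        v = integrate(lambda z: z * z * exg_lamb_pdf(z, lamb), -12, 40, order=64, panels=32)
        k = integrate(lambda z: z**3 * exg_lamb_pdf(z, lamb), -12, 40, order=64, panels=32)
        assert m == pytest.approx(0.0, abs=1e-8)
        assert v == pytest.approx(1.0, abs=1e-8)
        assert k == pytest.approx(2 * lamb**3, abs=1e-6)

    def test_gaussian_limit(self):
        z = np.linspace(-6, 6, 400)
        gap = np.max(np.abs(exg_lamb_pdf(z, 0.01) - gauss_pdf(z, 0.0, 1.0)))
        assert gap < 1e-4

    def test_low_asymmetry_within_one_percent_of_gaussian(self):
        # the lamb = 0.2 curve differs from the standard normal by < 1% of its peak
        z = np.linspace(-6, 6, 600)
        gap = np.max(np.abs(exg_lamb_pdf(z, 0.2) - gauss_pdf(z, 0.0, 1.0)))
        assert gap < 0.01 * gauss_pdf(0.0, 0.0, 1.0)

    def test_cdf_limit_and_quadrature(self):
        assert exg_lamb_cdf(60.0, 0.5) == pytest.approx(1.0, abs=1e-12)
        expected = integrate(lambda z: exg_lamb_pdf(z, 0.9), -12, 0, order=64, panels=16)
        assert exg_lamb_cdf(0.0, 0.9) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("lamb", [0.0, 1.0, -0.2, 1.3])
    def test_rejects_degenerate_asymmetry(self, lamb):
        with pytest.raises(ValueError):
            exg_lamb_pdf(0.0, lamb)
        with pytest.raises(ValueError):
            exg_lamb_cdf(0.0, lamb)


class TestParameterConversions:
    def test_table_values(self, elder_gng):
        st_ = pars_to_stats(elder_gng)
        assert st_.M == pytest.approx(831.14, abs=0.01)
        assert st_.S == pytest.approx(318.39, abs=0.01)
        assert st_.K == pytest.approx(1.79, abs=0.01)

    def test_trimmed_listing_values(self):
        st_ = pars_to_stats(ExGParams(453.52, 48.52, 140.29))
        assert st_.M == pytest.approx(593.80, abs=0.01)
        assert st_.S == pytest.approx(148.44, abs=0.01)
        assert st_.K == pytest.approx(1.69, abs=0.01)

    def test_gaussian_limit_of_stats(self):
        st_ = pars_to_stats(ExGParams(500.0, 50.0, 1e-9))
        assert st_.M == pytest.approx(500.0)
        assert st_.S == pytest.approx(50.0)
        assert st_.K == pytest.approx(0.0, abs=1e-20)

    def test_inversion_of_printed_moments(self):
        p = stats_to_pars(ExGStats(831.14, 318.95, 1.75))
        assert p.mu == pytest.approx(526.06, abs=0.15)
        assert p.sigma == pytest.approx(93.02, abs=0.15)
        assert p.tau == pytest.approx(305.08, abs=0.15)

    @pytest.mark.parametrize("K", [2.71, 2.0, 0.0, -0.5])
    def test_unrepresentable_skewness_raises(self, K):
        with pytest.raises(SkewnessRangeError):
            stats_to_pars(ExGStats(597.90, 169.90, K))

    @given(
        mu=st.floats(-1000, 2000),
        sigma=st.floats(1.0, 400.0),
        tau=st.floats(1.0, 600.0),
    )
    def test_round_trip(self, mu, sigma, tau):
        p = ExGParams(mu, sigma, tau)
        q = stats_to_pars(pars_to_stats(p))
        assert q.mu == pytest.approx(p.mu, rel=1e-10, abs=1e-8)
        assert q.sigma == pytest.approx(p.sigma, rel=1e-10)
        assert q.tau == pytest.approx(p.tau, rel=1e-10)
        assert 0.0 < pars_to_stats(p).K < 2.0

    @pytest.mark.parametrize("bad", [(0, 0, 1), (0, 1, 0), (0, -1, 1), (0, 1, -1)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ExGParams(*bad)


class TestQuantile:
    def test_worked_tail_point(self, young_gng):
        assert exg_quantile(1 - 0.001, young_gng) == pytest.approx(1472.84, abs=0.05)

    @pytest.mark.parametrize("p", [1e-4, 0.001, 0.5, 0.999])
    def test_inverse_identity(self, p):
        prm = ExGParams(0, 1, 1)
        assert exg_cdf(exg_quantile(p, prm), prm) == pytest.approx(p, abs=1e-9)

    def test_median_against_quadrature_bisection(self):
        # independent route: bisect on the quadrature-integrated CDF
        prm = ExGParams(0, 1, 1)

        def cdf_quad(x):
            return integrate(lambda t: exg_pdf(t, prm), -40.0, x, order=64, panels=32)

        lo, hi = -5.0, 10.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if cdf_quad(mid) < 0.5:
                lo = mid
            else:
                hi = mid
        assert exg_quantile(0.5, prm) == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range_probability(self, p):
        with pytest.raises(ValueError):
            exg_quantile(p, ExGParams(0, 1, 1))


class TestRootFinding:
    def test_simple_roots(self):
        assert find_zero(lambda x: x * x - 4, (0, 10), tol=1e-12) == pytest.approx(2.0, abs=1e-10)
        assert find_zero(math.cos, (0, 3), tol=1e-12) == pytest.approx(math.pi / 2, abs=1e-10)

    def test_consistent_with_quantile(self, true_params):
        st_ = pars_to_stats(true_params)
        root = find_zero(
            lambda x: exg_cdf(x, true_params) - 0.9,
            (st_.M - 10 * st_.S, st_.M + 20 * st_.S),
            tol=1e-12,
        )
        assert root == pytest.approx(exg_quantile(0.9, true_params), abs=1e-6)

    def test_rejects_bracket_without_sign_change(self):
        with pytest.raises(BracketError):
            find_zero(lambda x: x * x + 1, (0, 10))
        with pytest.raises(ValueError):
            find_zero(lambda x: x, (3, 3))


class TestQuadrature:
    def test_linear_exact_at_order_one(self):
        assert integrate(lambda x: x, 0, 1, order=1, panels=1) == pytest.approx(0.5, abs=1e-15)

    def test_polynomial_exactness(self):
        assert integrate(lambda x: x**5, 0, 1, order=3, panels=1) == pytest.approx(1 / 6, abs=1e-15)

    def test_gaussian_normalization(self):
        total = integrate(lambda t: gauss_pdf(t, 0, 1), -8, 8, order=64, panels=16)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_scalar_only_callable_supported(self):
        val = integrate(lambda x: math.sin(x), 0.0, math.pi, order=16, panels=4)
        assert val == pytest.approx(2.0, abs=1e-12)

    def test_rejects_bad_bounds(self):
        with pytest.raises(ValueError):
            integrate(lambda x: x, 1, 0)
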