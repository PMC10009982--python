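"""Skew-normal kernel: closed forms against independent quadrature and
scipy.stats.skewnorm oracles, plus the distributional invariants."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import integrate, stats

from dichoteff import (
    SNParams,
    TruncationBounds,
    sn_cdf,
    sn_mean,
    sn_pdf,
    sn_quantile,
    sn_sample,
    sn_variance,
    truncated_mean,
)

SQRT_2PI = math.sqrt(2 * math.pi)


def norm_pdf(x):
    return math.exp(-0.5 * x * x) / SQRT_2PI


def norm_cdf(x):
    return 0.5 * (1 + math.erf(x / math.sqrt(2)))


class TestDensity:
    @pytest.mark.parametrize("shape", [0.0, 1.0, -3.0, 7.0])
    def test_at_origin_shape_cancels(self, shape):
        # 2*phi(0)*Phi(0) = phi(0) regardless of the shape parameter
        assert sn_pdf(0.0, SNParams(0, 1, shape)) == pytest.approx(
            1 / SQRT_2PI, abs=1e-12
        )

    def test_formula_via_erf(self):
        # independent evaluation of 2*phi(1)*Phi(5) without scipy
        expected = 2 * norm_pdf(1.0) * norm_cdf(5.0)
        assert sn_pdf(1.0, SNParams(0, 1, 5)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("shape", [0.0, 2.0, -5.0, 20.0])
    def test_integrates_to_one(self, shape):
        p = SNParams(0, 1, shape)
        total, _ = integrate.quad(lambda x: sn_pdf(x, p), -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-9)

    @given(
        x=st.floats(-5, 5),
        shape=st.floats(-20, 20),
    )
    def test_reflection(self, x, shape):
        left = sn_pdf(x, SNParams(0, 1, shape))
        right = sn_pdf(-x, SNParams(0, 1, -shape))
        assert left == pytest.approx(right, rel=1e-12, abs=1e-300)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError, match="scale"):
            SNParams(0, 0.0, 1)
        with pytest.raises(ValueError, match="scale"):
            SNParams(0, -2.0, 1)


class TestCDF:
    def test_normal_median(self):
        assert sn_cdf(0.0, SNParams(0, 1, 0)) == pytest.approx(0.5, abs=1e-12)

    def test_owens_t_identity_at_zero(self):
        # F(0; shape) = 1/2 - arctan(shape)/pi; shape=1 gives exactly 1/4
        assert sn_cdf(0.0, SNParams(0, 1, 1)) == pytest.approx(0.25, abs=1e-12)
        for lam in (2.0, -4.0, 10.0):
            expected = 0.5 - math.atan(lam) / math.pi
            assert sn_cdf(0.0, SNParams(0, 1, lam)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("shape", [0.0, 1.0, 5.0, -10.0])
    def test_matches_pdf_quadrature(self, shape):
        p = SNParams(0, 1, shape)
        for x in (-2.0, -0.3, 0.8, 2.5):
            num, _ = integrate.quad(lambda t: sn_pdf(t, p), -np.inf, x)
            assert sn_cdf(x, p) == pytest.approx(num, abs=1e-8)

    @pytest.mark.parametrize("shape", [0.0, 3.0, -7.0])
    def test_matches_scipy_skewnorm(self, shape):
        p = SNParams(1.5, 2.0, shape)
        x = np.linspace(-6, 10, 25)
        np.testing.assert_allclose(
            sn_cdf(x, p), stats.skewnorm.cdf(x, shape, loc=1.5, scale=2.0), atol=1e-10
        )

    def test_limits(self):
        p = SNParams(0, 1, 4)
        assert sn_cdf(-40.0, p) == pytest.approx(0.0, abs=1e-12)
        assert sn_cdf(40.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_monotone(self):
        # Owen's T leaves noise at the 1e-16 level in the far tail, so allow it
        p = SNParams(0, 1, -6)
        x = np.linspace(-8, 8, 200)
        assert np.all(np.diff(sn_cdf(x, p)) >= -1e-12)


class TestQuantile:
    def test_normal_median(self):
        assert sn_quantile(0.5, SNParams(0, 1, 0)) == pytest.approx(0.0, abs=1e-10)

    def test_inverse_of_owens_anchor(self):
        assert sn_quantile(0.25, SNParams(0, 1, 1)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("shape", [-20.0, -5.0, 0.0, 1.0, 5.0, 20.0])
    def test_round_trip(self, shape):
        params = SNParams(2, 3, shape)
        for p in np.arange(0.01, 1.0, 0.07):
            x = sn_quantile(p, params)
            assert sn_cdf(x, params) == pytest.approx(p, abs=1e-8)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.3])
    def test_domain_error(self, p):
        with pytest.raises(ValueError, match="inside"):
            sn_quantile(p, SNParams(0, 1, 2))


class TestMoments:
    def test_mean_normal_and_half_normal_limit(self):
        assert sn_mean(SNParams(0, 1, 0)) == 0.0
        assert sn_mean(SNParams(0, 1, 1e8)) == pytest.approx(math.sqrt(2 / math.pi), rel=1e-8)
        assert sn_mean(SNParams(0, 1, -1e8)) == pytest.approx(-math.sqrt(2 / math.pi), rel=1e-8)

    @pytest.mark.parametrize("shape", [5.0, -2.0])
    def test_mean_matches_quadrature(self, shape):
        p = SNParams(0.7, 1.3, shape)
        num, _ = integrate.quad(lambda x: x * sn_pdf(x, p), -np.inf, np.inf)
        assert sn_mean(p) == pytest.approx(num, abs=1e-9)

    def test_variance_closed_form(self):
        assert sn_variance(SNParams(0, 1, 0)) == pytest.approx(1.0)
        assert sn_variance(SNParams(0, 2, 0)) == pytest.approx(4.0)
        assert sn_variance(SNParams(0, 1, 1e8)) == pytest.approx(1 - 2 / math.pi, rel=1e-8)

    @pytest.mark.parametrize("shape", [0.0, 2.0, 10.0, -5.0])
    def test_variance_matches_quadrature(self, shape):
        p = SNParams(0, 1, shape)
        mu = sn_mean(p)
        num, _ = integrate.quad(lambda x: (x - mu) ** 2 * sn_pdf(x, p), -np.inf, np.inf)
        assert sn_variance(p) == pytest.approx(num, abs=1e-7)


class TestNormalReduction:
    """shape = 0 must agree with the plain normal to 1e-10 everywhere."""

    def test_pdf_cdf_quantile(self):
        p = SNParams(1.2, 0.8, 0.0)
        x = np.linspace(-2, 4, 40)
        np.testing.assert_allclose(sn_pdf(x, p), stats.norm.pdf(x, 1.2, 0.8), atol=1e-10)
        np.testing.assert_allclose(sn_cdf(x, p), stats.norm.cdf(x, 1.2, 0.8), atol=1e-10)
        for q in (0.05, 0.3, 0.5, 0.9):
            assert sn_quantile(q, p) == pytest.approx(
                stats.norm.ppf(q, 1.2, 0.8), abs=1e-9
            )


class TestTruncatedMean:
    def test_half_normal_anchor(self):
        got = truncated_mean(SNParams(0, 1, 0), TruncationBounds(-np.inf, 0.0))
        assert got == pytest.approx(-math.sqrt(2 / math.pi), abs=1e-10)

    def test_untruncated_recovers_mean(self):
        p = SNParams(1, 2, 3)
        got = truncated_mean(p, TruncationBounds(-np.inf, np.inf))
        assert got == pytest.approx(sn_mean(p), abs=1e-10)

    def test_upper_tail_matches_quadrature(self):
        p = SNParams(0, 1, 5)
        u = sn_quantile(0.5, p)
        num, _ = integrate.quad(lambda x: x * sn_pdf(x, p), u, np.inf)
        assert truncated_mean(p, TruncationBounds(u, np.inf)) == pytest.approx(
            num / 0.5, abs=1e-8
        )

    # combinations chosen so the interval keeps representable probability mass
    DOUBLE_TRUNC_CASES = [
        (shape, bounds)
        for shape in (-10.0, -2.0, 0.0, 3.0, 15.0)
        for bounds in ((-1.2, 0.4), (0.0, 2.5), (-3.0, -0.5))
        if not (shape == 15.0 and bounds == (-3.0, -0.5))
    ]

    @pytest.mark.parametrize("shape,bounds", DOUBLE_TRUNC_CASES)
    def test_double_truncation_matches_quadrature(self, shape, bounds):
        p = SNParams(0, 1, shape)
        a, b = bounds
        num, _ = integrate.quad(lambda x: x * sn_pdf(x, p), a, b)
        mass = sn_cdf(b, p) - sn_cdf(a, p)
        got = truncated_mean(p, TruncationBounds(a, b))
        assert got == pytest.approx(num / mass, abs=1e-7)
        assert a < got < b

    @given(
        shape=st.floats(-20, 20),
        u=st.floats(-2.5, 2.5),
    )
    def test_law_of_total_expectation(self, shape, u):
        p = SNParams(0, 1, shape)
        tau = float(sn_cdf(u, p))
        # both sides of the split need representable mass at double precision
        assume(1e-12 < tau < 1 - 1e-12)
        below = truncated_mean(p, TruncationBounds(-np.inf, u))
        above = truncated_mean(p, TruncationBounds(u, np.inf))
        assert tau * below + (1 - tau) * above == pytest.approx(sn_mean(p), abs=1e-9)

    def test_zero_mass_interval_raises(self):
        with pytest.raises(ValueError, match="mass"):
            truncated_mean(SNParams(0, 1, 0), TruncationBounds(50.0, 51.0))

    def test_invalid_bounds(self):
        with pytest.raises(ValueError, match="lower"):
            TruncationBounds(1.0, 1.0)


class TestSampling:
    def test_deterministic_given_seed(self):
        p = SNParams(0, 1, 3)
        a = sn_sample(p, 5, seed=42)
        b = sn_sample(p, 5, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, sn_sample(p, 5, seed=43))

    def test_normal_case_ks(self):
        x = sn_sample(SNParams(0, 1, 0), 100_000, seed=1)
        assert stats.kstest(x, "norm").pvalue > 0.01

    @pytest.mark.parametrize("shape", [4.0, -4.0])
    def test_skewed_case_ks_and_moments(self, shape):
        p = SNParams(1.0, 2.0, shape)
        x = sn_sample(p, 100_000, seed=2)
        assert stats.kstest(x, lambda v: sn_cdf(v, p)).pvalue > 0.01
        se_mean = math.sqrt(sn_variance(p) / x.size)
        assert abs(x.mean() - sn_mean(p)) < 4 * se_mean
        assert math.copysign(1, stats.skew(x)) == math.copysign(1, shape)

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match=">= 1"):
            sn_sample(SNParams(0, 1, 0), 0, seed=0)
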