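"""Unit and property tests for the probability kernels."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from stoptf import (
    ExGaussParams,
    exgauss_cdf,
    exgauss_pdf,
    exgauss_sample,
    exgauss_sf,
    probit,
    probit_inv,
)
from stoptf.distributions import truncnorm_mean, truncnorm_pdf, truncnorm_sample


class TestExGaussPdf:
    def test_normalizes_to_one(self, go_params):
        total, _ = integrate.quad(
            lambda t: float(exgauss_pdf(t, go_params)), -2000, 6000, limit=400
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_convolution_oracle(self, go_params):
        # brute force: numerically convolve Normal(mu, sigma) with Exp(tau)
        mu, sig, tau = go_params.mu, go_params.sigma, go_params.tau
        for t in np.linspace(mu - 3 * sig, mu + tau + 6 * tau, 17):
            oracle, _ = integrate.quad(
                lambda x: stats.norm.pdf(x, mu, sig) * stats.expon.pdf(t - x, scale=tau),
                mu - 10 * sig, t, limit=300,
            )
            assert float(exgauss_pdf(t, go_params)) == pytest.approx(oracle, abs=1e-6)

    def test_matches_exponnorm(self, go_params, stop_params):
        # scipy's exponentially-modified normal is an independent implementation
        for p in (go_params, stop_params):
            k = p.tau / p.sigma
            t = np.linspace(p.mu - 4 * p.sigma, p.mu + 10 * p.tau, 200)
            ours = exgauss_pdf(t, p)
            ref = stats.exponnorm.pdf(t, k, loc=p.mu, scale=p.sigma)
            assert np.allclose(ours, ref, atol=1e-12, rtol=1e-9)

    def test_gaussian_limit_small_tau(self):
        p = ExGaussParams(mu=400.0, sigma=50.0, tau=50.0 * 1e-6)
        t = np.linspace(250, 550, 60)
        assert np.allclose(exgauss_pdf(t, p), stats.norm.pdf(t, 400, 50), atol=1e-6)

    def test_deep_right_tail_finite(self, stop_params):
        # far in the exponential tail the log-pdf must remain finite and linear
        lp = np.asarray([
            float(np.log(exgauss_pdf(t, stop_params))) if exgauss_pdf(t, stop_params) > 0
            else float("-inf")
            for t in (5000.0, 10000.0)
        ])
        from stoptf.distributions import exgauss_logpdf

        lp = exgauss_logpdf(np.array([5000.0, 10000.0]), stop_params)
        assert np.all(np.isfinite(lp))
        slope = (lp[1] - lp[0]) / 5000.0
        assert slope == pytest.approx(-1 / stop_params.tau, rel=1e-3)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            ExGaussParams(mu=400, sigma=-1, tau=50)
        with pytest.raises(ValueError):
            ExGaussParams(mu=400, sigma=50, tau=0)


class TestExGaussCdf:
    def test_limits(self, go_params):
        assert float(exgauss_cdf(-1e9, go_params)) == pytest.approx(0.0, abs=1e-10)
        assert float(exgauss_cdf(1e9, go_params)) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quadrature_of_pdf(self, go_params):
        for t in (300.0, 450.0, 520.0, 700.0, 1100.0):
            oracle, _ = integrate.quad(
                lambda x: float(exgauss_pdf(x, go_params)), -2000, t, limit=400
            )
            assert float(exgauss_cdf(t, go_params)) == pytest.approx(oracle, abs=1e-7)

    def test_gaussian_limit(self):
        p = ExGaussParams(mu=400.0, sigma=50.0, tau=50.0 * 1e-6)
        t = np.linspace(250, 550, 30)
        assert np.allclose(exgauss_cdf(t, p), stats.norm.cdf(t, 400, 50), atol=1e-6)

    def test_sf_complements_cdf(self, stop_params):
        t = np.linspace(-100, 1500, 300)
        assert np.allclose(exgauss_cdf(t, stop_params) + exgauss_sf(t, stop_params), 1.0, atol=1e-12)

    @given(
        mu=st.floats(100, 800), sigma=st.floats(5, 200), tau=st.floats(5, 300),
    )
    def test_monotone_and_bounded(self, mu, sigma, tau):
        p = ExGaussParams(mu=mu, sigma=sigma, tau=tau)
        t = np.linspace(mu - 6 * sigma, mu + tau + 8 * (sigma + tau), 120)
        c = exgauss_cdf(t, p)
        assert np.all(np.diff(c) >= -1e-12)
        assert np.all((c >= 0) & (c <= 1))


class TestExGaussSampler:
    def test_moments(self, go_params, rng):
        n = 1_000_000
        x = exgauss_sample(n, go_params, rng)
        se_mean = np.sqrt(go_params.var / n)
        assert abs(x.mean() - go_params.mean) < 3 * se_mean
        # variance SE via fourth-moment normal-ish approximation
        se_var = go_params.var * np.sqrt(2 / n) * 2
        assert abs(x.var() - go_params.var) < 3 * se_var

    def test_ecdf_agrees_with_cdf(self, stop_params, rng):
        n = 100_000
        x = np.sort(exgauss_sample(n, stop_params, rng))
        ecdf = np.arange(1, n + 1) / n
        dist = np.max(np.abs(ecdf - exgauss_cdf(x, stop_params)))
        assert dist < 1.63 / np.sqrt(n)  # KS critical value, alpha = 0.01


class TestProbit:
    def test_half_maps_to_zero(self):
        assert float(probit(0.5)) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.9])
    def test_round_trip(self, p):
        assert float(probit_inv(probit(p))) == pytest.approx(p, abs=1e-12)

    def test_truncation_range(self):
        # +-6 on the probit scale bounds the attainable P(TF) range
        assert float(probit_inv(-6.0)) == pytest.approx(stats.norm.cdf(-6.0), rel=1e-12)
        assert float(probit_inv(-6.0)) == pytest.approx(9.9e-10, rel=0.02)
        assert float(probit_inv(6.0)) == pytest.approx(1 - 9.9e-10, abs=1e-11)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            probit(0.0)
        with pytest.raises(ValueError):
            probit(1.5)


class TestTruncNorm:
    def test_normalizes(self):
        total, _ = integrate.quad(
            lambda x: float(truncnorm_pdf(x, 0, 1000, 200, 100)), 0, 1000, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_flat_limit(self):
        val = float(truncnorm_pdf(432.1, 0, 1000, 500, 1e6))
        assert val == pytest.approx(0.001, abs=1e-6)

    def test_zero_outside_support(self):
        assert float(truncnorm_pdf(-5.0, 0, 1000, 200, 100)) == 0.0
        assert float(truncnorm_pdf(1005.0, 0, 1000, 200, 100)) == 0.0

    def test_sample_mean_matches_closed_form(self, rng):
        n = 1_000_000
        x = truncnorm_sample(n, 0, 1000, 200, 100, rng)
        target = truncnorm_mean(0, 1000, 200, 100)
        ref = stats.truncnorm(-2.0, 8.0, loc=200, scale=100)
        assert target == pytest.approx(ref.mean(), rel=1e-10)
        assert abs(x.mean() - target) < 3 * ref.std() / np.sqrt(n)

    def test_degenerate_interval_raises(self):
        with pytest.raises(ValueError):
            truncnorm_pdf(0.5, 10, 10, 0, 1)
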