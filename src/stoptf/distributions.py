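"""Probability kernels shared by the simulator, likelihood, and sampler.

The ex-Gaussian — the sum of a Gaussian(mu, sigma) and an independent
Exponential(tau) random variable — is the standard parametric description of
response-time distributions used here for both go RTs and stop-signal RTs
(SSRTs).  mu and sigma capture the leading edge of the distribution, tau its
slow exponential tail; the mean is mu + tau and the variance sigma^2 + tau^2.

All densities are evaluated through the scaled complementary error function
(erfcx), which keeps the pdf/cdf finite for sigma/tau ratios where the naive
exp(...) * Phi(...) product overflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "ExGaussParams",
    "exgauss_logpdf",
    "exgauss_pdf",
    "exgauss_cdf",
    "exgauss_sf",
    "exgauss_sample",
    "probit",
    "probit_inv",
    "truncnorm_logpdf",
    "truncnorm_pdf",
    "truncnorm_sample",
    "truncnorm_mean",
]

_SQRT2 = np.sqrt(2.0)
_LOG2 = np.log(2.0)
# below this tau/sigma (sigma/tau) ratio the exponential (Gaussian) component
# is numerically invisible; fall back to the pure limiting distribution
_RATIO_FLOOR = 1e-4
# erfcx(w) for w << 0 approaches 2*exp(w^2); switch to the log-space asymptote
# before exp(w^2) overflows
_ERFCX_NEG_CUT = -25.0


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of one ex-Gaussian RT distribution, in milliseconds."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def var(self) -> float:
        return self.sigma**2 + self.tau**2


def _as_params(p) -> tuple[float, float, float]:
    if isinstance(p, ExGaussParams):
        return p.mu, p.sigma, p.tau
    mu, sigma, tau = p
    if not (sigma > 0 and tau > 0):
        raise ValueError("sigma and tau must be > 0")
    return float(mu), float(sigma), float(tau)


def _logpdf_core(t, mu: float, sigma: float, tau: float):
    """Branch-lean log-pdf kernel shared by the public wrappers."""
    z = (t - mu) / sigma
    if tau < _RATIO_FLOOR * sigma:
        # pure-Gaussian limit
        return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    if sigma < _RATIO_FLOOR * tau:
        # pure-exponential limit (shifted at mu)
        with np.errstate(divide="ignore"):
            return np.where(t >= mu, -(t - mu) / tau - np.log(tau), -np.inf)
    u = sigma / tau
    w = (u - z) / _SQRT2
    out = np.log(special.erfcx(np.maximum(w, _ERFCX_NEG_CUT)))
    out += -np.log(2 * tau) - 0.5 * z * z
    bad = w < _ERFCX_NEG_CUT  # deep right tail: exponential asymptote
    if bad.any():
        tail = -np.log(2 * tau) - 0.5 * z * z + _LOG2 + w * w
        out = np.where(bad, tail, out)
    return out


def exgauss_logpdf(t, p):
    """Log density of the ex-Gaussian at ``t`` (ms).

    Uses ``f(t) = erfcx((u - z)/sqrt(2)) * exp(-z^2/2) / (2 tau)`` with
    z = (t - mu)/sigma and u = sigma/tau, which is exact and overflow-free
    except deep in the right tail, where the exponential-tail asymptote
    ``log f = -log tau + u^2/2 - u z`` takes over.
    """
    mu, sigma, tau = _as_params(p)
    return _logpdf_core(np.asarray(t, dtype=float), mu, sigma, tau)


def exgauss_pdf(t, p):
    """Ex-Gaussian probability density (1/ms)."""
    mu, sigma, tau = _as_params(p)
    return np.exp(_logpdf_core(np.asarray(t, dtype=float), mu, sigma, tau))


def exgauss_sf(t, p):
    """Survival function 1 - F(t).

    Uses the identity ``1 - F(t) = Phi(-z) + tau * f(t)``: both terms are
    nonnegative, so the right tail never suffers cancellation.  This is the
    form the race likelihood consumes for 1 - F_stop.
    """
    mu, sigma, tau = _as_params(p)
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma
    if tau < _RATIO_FLOOR * sigma:
        return special.ndtr(-z)
    out = special.ndtr(-z) + tau * np.exp(_logpdf_core(t, mu, sigma, tau))
    return np.minimum(out, 1.0)


def exgauss_cdf(t, p):
    """Ex-Gaussian distribution function F(t) = Phi(z) - tau * f(t)."""
    mu, sigma, tau = _as_params(p)
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma
    if tau < _RATIO_FLOOR * sigma:
        return special.ndtr(z)
    out = special.ndtr(z) - tau * np.exp(_logpdf_core(t, mu, sigma, tau))
    return np.clip(out, 0.0, 1.0)


def exgauss_sample(n: int, p, rng) -> np.ndarray:
    """Draw ``n`` ex-Gaussian variates: Gaussian plus exponential."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu, sigma, tau = _as_params(p)
    rng = np.random.default_rng(rng)
    return rng.normal(mu, sigma, n) + rng.exponential(tau, n)


def probit(p):
    """Probit transform: inverse standard-normal cdf, mapping (0,1) -> R."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probit requires 0 < p < 1")
    return special.ndtri(p)


def probit_inv(z):
    """Inverse probit: standard-normal cdf, mapping R -> (0,1)."""
    return special.ndtr(np.asarray(z, dtype=float))


def _truncnorm_ab(lo: float, hi: float, mean: float, sd: float):
    if not lo < hi:
        raise ValueError(f"degenerate truncation interval [{lo}, {hi}]")
    if not sd > 0:
        raise ValueError("sd must be > 0")
    return (lo - mean) / sd, (hi - mean) / sd


def truncnorm_logpdf(x, lo, hi, mean, sd):
    """Log density of a Normal(mean, sd) truncated to [lo, hi].

    Written directly in terms of the normal log-density and the log of the
    interval mass (via ``log_ndtr``) so that it stays finite when the
    truncation interval sits many sds from ``mean``.
    """
    a, b = _truncnorm_ab(lo, hi, mean, sd)
    x = np.asarray(x, dtype=float)
    z = (x - mean) / sd
    # log(Phi(b) - Phi(a)) computed stably from log_ndtr of whichever tail
    # representation is better conditioned
    if a > 0:  # both bounds in the upper tail: use survival forms
        log_mass = special.log_ndtr(-a) + np.log1p(
            -np.exp(special.log_ndtr(-b) - special.log_ndtr(-a))
        )
    else:
        log_mass = special.log_ndtr(b) + np.log1p(
            -np.exp(special.log_ndtr(a) - special.log_ndtr(b))
        )
    core = -0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi) - log_mass
    return np.where((x >= lo) & (x <= hi), core, -np.inf)


def truncnorm_pdf(x, lo, hi, mean, sd):
    with np.errstate(over="ignore"):
        return np.exp(truncnorm_logpdf(x, lo, hi, mean, sd))


def truncnorm_sample(n: int, lo, hi, mean, sd, rng) -> np.ndarray:
    """Draw from the truncated normal by inverse-cdf sampling."""
    a, b = _truncnorm_ab(lo, hi, mean, sd)
    rng = np.random.default_rng(rng)
    fa, fb = special.ndtr(a), special.ndtr(b)
    u = rng.uniform(fa, fb, size=n)
    return np.clip(mean + sd * special.ndtri(u), lo, hi)


def truncnorm_mean(lo, hi, mean, sd) -> float:
    """Closed-form mean of the truncated normal (used as a moment oracle)."""
    a, b = _truncnorm_ab(lo, hi, mean, sd)
    phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
    mass = special.ndtr(b) - special.ndtr(a)
    return mean + sd * (phi(a) - phi(b)) / mass
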