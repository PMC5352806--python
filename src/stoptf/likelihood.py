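"""Exact per-trial likelihood of the trigger-failure race model.

Three trial types contribute:

* go trials — plain ex-Gaussian go density f_go(t);
* signal-respond trials — the mixture
  ``ptf * f_go(t) + (1 - ptf) * [1 - F_stop(t - SSD)] * f_go(t)``:
  a response slips through either because the stop process was never
  triggered, or because it was triggered but finished after the go process;
* successful inhibitions — ``(1 - ptf) * \\int [1 - F_go(t)] f_stop(t - SSD) dt``,
  the probability that a triggered stop process beats the go process,
  integrated over the unobservable stop finishing time.

The inhibition integral doubles as the normalising constant of the censored
signal-respond density, so for every (params, SSD) pair the signal-respond
density mass plus the inhibition probability equals one.

F_stop / f_stop are parameterised on the finishing-time axis by the shift
t -> t - SSD: the SSRT distribution itself is SSD-invariant, only the stop
process's finishing time moves with the delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate

from .distributions import (
    ExGaussParams,
    exgauss_cdf,
    exgauss_logpdf,
    exgauss_pdf,
    exgauss_sf,
)
from .params import SubjectParams
from .simulate import validate_trial_table

__all__ = [
    "LikelihoodSettings",
    "loglik_go",
    "loglik_signal_respond",
    "loglik_inhibit",
    "total_loglik",
    "inhibit_prob",
    "respond_prob",
    "signal_respond_logdensity",
    "split_trials",
]


@dataclass(frozen=True)
class LikelihoodSettings:
    """Numerical knobs for the inhibition integral and underflow handling.

    method
        ``"gauss-legendre"`` — fixed-order rule on a finite window covering
        the stop density's effective support, with analytic corrections for
        the mass the window clips off (default; fast enough for MCMC);
        ``"adaptive"`` — scipy's adaptive Gauss–Kronrod quadrature on the
        same window (reference-quality, used for one-off evaluations).
    n_nodes
        Gauss–Legendre order.
    k_lower, k_upper
        Window half-widths: the window is
        ``[SSD + mu_stop - k_lower * sigma_stop,
           SSD + mu_stop + k_upper * (sigma_stop + tau_stop)]``.
    floor
        Per-trial likelihood floor applied before the log, so a pathological
        proposal yields a very small finite log-likelihood rather than -inf.
    """

    method: str = "gauss-legendre"
    n_nodes: int = 128
    k_lower: float = 12.0
    k_upper: float = 16.0
    epsabs: float = 1e-12
    floor: float = 1e-300


DEFAULT_SETTINGS = LikelihoodSettings()


@lru_cache(maxsize=8)
def _leggauss(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _window(stop: ExGaussParams, ssd, s: LikelihoodSettings):
    lo = ssd + stop.mu - s.k_lower * stop.sigma
    hi = ssd + stop.mu + s.k_upper * (stop.sigma + stop.tau)
    return lo, hi


def inhibit_prob(ssds, sp: SubjectParams, settings: LikelihoodSettings | None = None):
    """P(successful inhibition | stop trial) for each SSD.

    Equals ``(1 - ptf)`` times the probability that a triggered stop process
    finishes before the go process, ``\\int [1 - F_go(t)] f_stop(t - SSD) dt``.
    """
    s = settings or DEFAULT_SETTINGS
    scalar = np.isscalar(ssds) or np.ndim(ssds) == 0
    ssds = np.atleast_1d(np.asarray(ssds, dtype=float))
    if s.method == "adaptive":
        vals = np.array([_inhibit_integral_adaptive(d, sp, s) for d in ssds])
    else:
        vals = _inhibit_integral_gl(ssds, sp, s)
    out = (1.0 - sp.ptf) * np.clip(vals, 0.0, 1.0)
    return float(out[0]) if scalar else out


def _tail_corrections(ssds, sp, lo, hi):
    # mass of f_stop clipped below the window (where 1 - F_go ~ S_go(lo))
    # and above it (where the integrand is S_go * stop tail)
    low = exgauss_cdf(lo - ssds, sp.stop) * exgauss_sf(lo, sp.go)
    high = exgauss_sf(hi - ssds, sp.stop) * exgauss_sf(hi, sp.go)
    return low + high


def _inhibit_integral_gl(ssds, sp, s):
    x, w = _leggauss(s.n_nodes)
    lo, hi = _window(sp.stop, ssds, s)
    half = 0.5 * (hi - lo)
    t = lo[:, None] + half[:, None] * (x[None, :] + 1.0)
    integrand = exgauss_sf(t, sp.go) * exgauss_pdf(t - ssds[:, None], sp.stop)
    vals = half * (integrand @ w)
    return vals + _tail_corrections(ssds, sp, lo, hi)


def _inhibit_integral_adaptive(ssd, sp, s):
    lo, hi = _window(sp.stop, ssd, s)
    f = lambda t: float(exgauss_sf(t, sp.go) * exgauss_pdf(t - ssd, sp.stop))
    val, _ = integrate.quad(f, lo, hi, epsabs=s.epsabs, limit=200)
    return val + float(_tail_corrections(np.array([ssd]), sp, np.array([lo]), np.array([hi]))[0])


def respond_prob(sp: SubjectParams, ssds, settings: LikelihoodSettings | None = None):
    """P(response | stop trial) at each SSD: ptf + (1 - ptf) * P(go wins race)."""
    return 1.0 - inhibit_prob(ssds, sp, settings)


def signal_respond_logdensity(rts, ssds, sp: SubjectParams,
                              settings: LikelihoodSettings | None = None):
    """Per-trial log density of signal-respond RTs (the Eq.-style mixture)."""
    s = settings or DEFAULT_SETTINGS
    rts = np.asarray(rts, dtype=float)
    ssds = np.asarray(ssds, dtype=float)
    f_go = exgauss_pdf(rts, sp.go)
    s_stop = exgauss_sf(rts - ssds, sp.stop)
    dens = (sp.ptf + (1.0 - sp.ptf) * s_stop) * f_go
    return np.log(np.maximum(dens, s.floor))


def loglik_go(rts, go: ExGaussParams, settings: LikelihoodSettings | None = None) -> float:
    """Summed log-likelihood of the (correct) go RTs."""
    s = settings or DEFAULT_SETTINGS
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        return 0.0
    lp = exgauss_logpdf(rts, go)
    return float(np.sum(np.maximum(lp, np.log(s.floor))))


def loglik_signal_respond(rts, ssds, sp: SubjectParams,
                          settings: LikelihoodSettings | None = None) -> float:
    rts = np.asarray(rts, dtype=float)
    ssds = np.asarray(ssds, dtype=float)
    if rts.shape != ssds.shape:
        raise ValueError("signal-respond RTs and SSDs must align")
    if rts.size == 0:
        return 0.0
    return float(np.sum(signal_respond_logdensity(rts, ssds, sp, settings)))


def loglik_inhibit(ssds, sp: SubjectParams,
                   settings: LikelihoodSettings | None = None) -> float:
    s = settings or DEFAULT_SETTINGS
    ssds = np.asarray(ssds, dtype=float)
    if ssds.size == 0:
        return 0.0
    uniq, counts = np.unique(ssds, return_counts=True)
    p = inhibit_prob(uniq, sp, s)
    return float(np.sum(counts * np.log(np.maximum(p, s.floor))))


def split_trials(df) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split a single-subject trial table into (go_rts, sr_rts, sr_ssds, inh_ssds)."""
    validate_trial_table(df)
    if df["subject"].nunique() > 1:
        raise ValueError("expected a single-subject trial table")
    is_stop = df["is_stop"].astype(bool)
    responded = df["responded"].astype(bool)
    go_rts = df.loc[~is_stop, "rt"].to_numpy(float)
    sr = df.loc[is_stop & responded]
    inh = df.loc[is_stop & ~responded]
    return (
        go_rts,
        sr["rt"].to_numpy(float),
        sr["ssd"].to_numpy(float),
        inh["ssd"].to_numpy(float),
    )


def total_loglik(df, sp: SubjectParams,
                 settings: LikelihoodSettings | None = None) -> float:
    """Full log-likelihood of one participant's trial table."""
    go_rts, sr_rts, sr_ssds, inh_ssds = split_trials(df)
    return (
        loglik_go(go_rts, sp.go, settings)
        + loglik_signal_respond(sr_rts, sr_ssds, sp, settings)
        + loglik_inhibit(inh_ssds, sp, settings)
    )
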