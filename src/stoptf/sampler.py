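"""Metropolis-within-Gibbs posterior sampling for the race models.

Each scalar parameter gets its own Gaussian random-walk Metropolis block
(true "within-Gibbs" blocking).  Proposal SDs adapt toward a 0.44 acceptance
rate during burn-in — the standard target for one-dimensional random-walk
updates — and are frozen afterwards, so the retained draws target the exact
posterior.  The six RT parameters are sampled on their natural millisecond
scale; P(TF) is sampled on the probit scale in every model variant (with the
uniform prior mapped through the change of variables), which gives the
random walk sensible geometry when P(TF) sits near zero.

The expensive part of each posterior evaluation is the inhibition integral,
so per-subject likelihood terms are cached by which parameters they depend
on: a block update recomputes only the pieces its parameter touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .distributions import exgauss_pdf, exgauss_sf
from .likelihood import (
    DEFAULT_SETTINGS,
    LikelihoodSettings,
    _inhibit_integral_gl,
    split_trials,
)
from .models import RT_PARAMS, PriorSpec
from .params import PARAM_NAMES, GroupParams, SubjectParams

__all__ = ["SamplerSettings", "PosteriorChains", "fit", "mwg_step", "rhat"]


@dataclass(frozen=True)
class SamplerSettings:
    """Chain configuration; defaults retain 3 x 2,000 = 6,000 draws."""

    n_chains: int = 3
    n_burnin: int = 2000
    n_retained: int = 2000
    thin: int = 1
    adapt_interval: int = 50
    target_accept: float = 0.44
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_retained <= 0:
            raise ValueError("n_retained must be > 0")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence assessment")


@dataclass
class PosteriorChains:
    """Per-chain, per-iteration posterior draws plus sampling metadata."""

    draws: np.ndarray  # (chain, iteration, parameter)
    param_names: list
    model: str
    n_burnin: int
    seed: int | None
    accept_rates: dict = field(default_factory=dict)
    proposal_sds: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def get(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, flattened across chains."""
        return self.draws[:, :, self.param_names.index(name)].ravel()

    def per_chain(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.param_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        n_chain, n_iter, _ = self.draws.shape
        df = pd.DataFrame(
            self.draws.reshape(n_chain * n_iter, -1), columns=self.param_names
        )
        df.insert(0, "iteration", np.tile(np.arange(n_iter), n_chain))
        df.insert(0, "chain", np.repeat(np.arange(n_chain), n_iter))
        return df

    def rhat_table(self) -> pd.DataFrame:
        rows = [(p, rhat(self, p)) for p in self.param_names]
        return pd.DataFrame(rows, columns=["parameter", "rhat"])


def rhat(chains: PosteriorChains | np.ndarray, parameter: str | None = None) -> float:
    """Gelman–Rubin potential scale reduction factor.

    Classic between/within form: with m chains of length n,
    ``Vhat = (n - 1)/n * W + B/n`` and ``R-hat = sqrt(Vhat / W)``.
    Returns NaN when the within-chain variance is zero (undefined).
    """
    if isinstance(chains, PosteriorChains):
        x = chains.per_chain(parameter)
    else:
        x = np.asarray(chains, dtype=float)
    m, n = x.shape
    if m < 2:
        raise ValueError("R-hat needs at least two chains")
    w = np.mean(np.var(x, axis=1, ddof=1))
    if w == 0:
        return float("nan")
    b = n * np.var(np.mean(x, axis=1), ddof=1)
    vhat = (n - 1) / n * w + b / n
    return float(np.sqrt(vhat / w))


def mwg_step(theta, log_target, proposal_sds, rng):
    """One Metropolis-within-Gibbs sweep over a generic scalar target.

    Updates each coordinate in turn with a Gaussian random-walk proposal and
    a Metropolis accept/reject against ``log_target``.  Returns the new state
    and the per-coordinate acceptance flags.  This is the reference update
    rule; the model fits use an equivalent cached fast path.
    """
    theta = np.array(theta, dtype=float)
    accepted = np.zeros(len(theta), dtype=bool)
    lp = log_target(theta)
    for k in range(len(theta)):
        prop = theta.copy()
        prop[k] += proposal_sds[k] * rng.standard_normal()
        lp_prop = log_target(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp, accepted[k] = prop, lp_prop, True
    return theta, accepted


# --------------------------------------------------------------------------
# cached single-subject likelihood
# --------------------------------------------------------------------------

class _SubjectLik:
    """Per-subject likelihood with caching by parameter block.

    Pieces: the summed go-trial log density (go triple); the go density and
    the stop survival at the signal-respond RTs (go / stop triples); and the
    inhibition integral per unique SSD (both triples).  P(TF) enters only in
    the final mixture assembly, so its block is nearly free.
    """

    def __init__(self, df, settings: LikelihoodSettings):
        self.s = settings
        go_rts, sr_rts, sr_ssds, inh_ssds = split_trials(df)
        self.go_rts = go_rts
        self.sr_rts = sr_rts
        self.sr_ssds = sr_ssds
        self.sr_lag = sr_rts - sr_ssds
        self.inh_uniq, self.inh_counts = np.unique(inh_ssds, return_counts=True)
        self.n_stop = len(sr_rts) + int(self.inh_counts.sum())
        self._log_floor = np.log(settings.floor)

    def pieces(self, sp: SubjectParams) -> dict:
        from .likelihood import loglik_go

        return {
            "go_sum": loglik_go(self.go_rts, sp.go, self.s),
            "fgo_sr": exgauss_pdf(self.sr_rts, sp.go),
            "sstop_sr": exgauss_sf(self.sr_lag, sp.stop),
            "integral": _inhibit_integral_gl(self.inh_uniq, sp, self.s)
            if len(self.inh_uniq)
            else np.empty(0),
        }

    def update_pieces(self, pieces: dict, sp: SubjectParams, changed: str) -> dict:
        """Recompute only the pieces that depend on the changed block."""
        from .likelihood import loglik_go

        out = dict(pieces)
        if changed == "go":
            out["go_sum"] = loglik_go(self.go_rts, sp.go, self.s)
            out["fgo_sr"] = exgauss_pdf(self.sr_rts, sp.go)
        elif changed == "stop":
            out["sstop_sr"] = exgauss_sf(self.sr_lag, sp.stop)
        if changed in ("go", "stop") and len(self.inh_uniq):
            out["integral"] = _inhibit_integral_gl(self.inh_uniq, sp, self.s)
        return out

    def loglik(self, pieces: dict, ptf: float) -> float:
        total = pieces["go_sum"]
        if len(self.sr_rts):
            dens = (ptf + (1.0 - ptf) * pieces["sstop_sr"]) * pieces["fgo_sr"]
            total += float(
                np.sum(np.maximum(np.log(np.maximum(dens, self.s.floor)), self._log_floor))
            )
        if len(self.inh_uniq):
            p = (1.0 - ptf) * np.clip(pieces["integral"], 0.0, 1.0)
            total += float(
                np.sum(self.inh_counts * np.log(np.maximum(p, self.s.floor)))
            )
        return total


_BLOCK_OF = {  # which cache group each sampled coordinate belongs to
    0: "go", 1: "go", 2: "go", 3: "stop", 4: "stop", 5: "stop", 6: "ptf",
}


def _sp_from_theta(theta) -> SubjectParams:
    from .distributions import ExGaussParams

    ptf = float(special.ndtr(theta[6])) if len(theta) == 7 else 0.0
    return SubjectParams(
        go=ExGaussParams(theta[0], theta[1], theta[2]),
        stop=ExGaussParams(theta[3], theta[4], theta[5]),
        ptf=ptf,
    )


def _log_prior_theta(theta, prior: PriorSpec) -> float:
    """Prior on the sampling scale: uniforms in ms, N(0,1) density on z_tf."""
    for value, name in zip(theta[:6], RT_PARAMS):
        lo, hi = prior.bounds[name]
        if not lo <= value <= hi:
            return -np.inf
    total = 0.0
    if len(theta) == 7:
        z = theta[6]
        # ptf ~ U(0, 1) mapped through ptf = Phi(z)
        total += -0.5 * z * z - 0.5 * np.log(2 * np.pi)
    return total


def _moment_init(lik: _SubjectLik, prior: PriorSpec, rng, with_ptf: bool) -> np.ndarray:
    """Data-informed overdispersed start values (jittered per chain)."""
    go = lik.go_rts if len(lik.go_rts) else lik.sr_rts
    m, sd = float(np.mean(go)), float(np.std(go) + 1e-6)
    tau0 = 0.8 * sd
    mu0 = m - tau0
    sig0 = np.sqrt(max(sd**2 - tau0**2, (0.2 * sd) ** 2))
    ssds = np.r_[lik.sr_ssds, np.repeat(lik.inh_uniq, lik.inh_counts)]
    mean_ssrt = np.clip(m - (np.mean(ssds) if len(ssds) else m / 2), 80.0, 600.0)
    start = {
        "mu_go": mu0, "sigma_go": sig0, "tau_go": tau0,
        "mu_stop": 0.75 * mean_ssrt, "sigma_stop": 0.2 * mean_ssrt,
        "tau_stop": 0.25 * mean_ssrt,
    }
    theta = []
    for name in RT_PARAMS:
        lo, hi = prior.bounds[name]
        v = start[name] * np.exp(0.1 * rng.standard_normal())
        theta.append(float(np.clip(v, lo + 1e-3 * (hi - lo), hi - 1e-3 * (hi - lo))))
    if with_ptf:
        ptf0 = float(np.clip(0.08 * np.exp(0.5 * rng.standard_normal()), 0.005, 0.5))
        theta.append(float(special.ndtri(ptf0)))
    return np.array(theta)


class _Adapter:
    """Robbins–Monro tuning of per-block log proposal SDs during burn-in."""

    def __init__(self, sds, interval: int, target: float):
        self.log_sd = np.log(np.asarray(sds, dtype=float))
        self.interval = interval
        self.target = target
        self.accepts = np.zeros(len(sds))
        self.count = 0
        self.round = 0
        self.frozen = False

    @property
    def sds(self) -> np.ndarray:
        return np.exp(self.log_sd)

    def record(self, accepted: np.ndarray) -> None:
        if self.frozen:
            return
        self.accepts += accepted
        self.count += 1
        if self.count >= self.interval:
            self.round += 1
            rate = self.accepts / self.count
            step = max(0.05, 1.0 / np.sqrt(self.round))
            self.log_sd += step * (rate - self.target)
            self.log_sd = np.clip(self.log_sd, -10.0, 7.0)
            self.accepts[:] = 0.0
            self.count = 0


def _init_proposal_sds(theta, with_ptf: bool) -> np.ndarray:
    sds = np.maximum(0.05 * np.abs(theta[:6]), 1.0)
    if with_ptf:
        sds = np.r_[sds, 0.15]
    return sds


class _JointAdapter:
    """Adaptive full-vector random-walk proposal.

    Scalar blocks explore the full conditionals but mix slowly along the
    strong posterior correlations of the ex-Gaussian parameters (mu vs tau in
    particular), so each sweep also makes one multivariate-normal proposal
    whose covariance is estimated from the burn-in history (scaled by the
    classic 2.38^2/d factor, with a Robbins–Monro tweak toward 0.23
    acceptance).  Adaptation freezes with the scalar blocks at the end of
    burn-in, so the retained draws target the exact posterior.
    """

    def __init__(self, free_idx, interval: int):
        self.free = np.asarray(free_idx, dtype=int)
        self.interval = interval
        self.history: list = []
        self.chol: np.ndarray | None = None
        self.log_scale = 0.0
        self.accepts = 0
        self.count = 0
        self.round = 0
        self.frozen = False

    def observe(self, theta) -> None:
        if not self.frozen:
            self.history.append(theta[self.free].copy())

    def maybe_update(self) -> None:
        d = len(self.free)
        if self.frozen or len(self.history) < max(100, 10 * d):
            return
        if len(self.history) % self.interval:
            return
        hist = np.asarray(self.history[len(self.history) // 2:])
        cov = np.cov(hist.T) * (2.38**2 / d)
        cov += 1e-10 * np.eye(d) * np.trace(cov)
        try:
            self.chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            self.chol = None

    def propose(self, theta, rng) -> np.ndarray | None:
        if self.chol is None:
            return None
        prop = theta.copy()
        step = np.exp(self.log_scale) * (self.chol @ rng.standard_normal(len(self.free)))
        prop[self.free] += step
        return prop

    def record(self, accepted: bool) -> None:
        if self.frozen:
            return
        self.accepts += accepted
        self.count += 1
        if self.count >= self.interval:
            self.round += 1
            rate = self.accepts / self.count
            self.log_scale += max(0.05, 1.0 / np.sqrt(self.round)) * (rate - 0.23)
            self.accepts = 0
            self.count = 0


def _run_individual_chain(lik, prior, settings, lik_settings, rng, model,
                          fixed_idx, theta0):
    with_ptf = model == "individual"
    n_par = 7 if with_ptf else 6
    theta = theta0.copy()
    sp = _sp_from_theta(theta)
    pieces = lik.pieces(sp)
    cur_loglik = lik.loglik(pieces, sp.ptf)
    cur_prior = _log_prior_theta(theta, prior)

    adapter = _Adapter(_init_proposal_sds(theta, with_ptf),
                       settings.adapt_interval, settings.target_accept)
    free = [k for k in range(n_par) if k not in fixed_idx]
    joint = _JointAdapter(free, settings.adapt_interval)
    n_iter = settings.n_burnin + settings.n_retained * settings.thin
    out = np.empty((settings.n_retained, n_par))
    accept_totals = np.zeros(n_par)
    kept = 0

    for it in range(n_iter):
        accepted = np.zeros(n_par)
        for k in free:
            prop = theta.copy()
            prop[k] += adapter.sds[k] * rng.standard_normal()
            prop_prior = _log_prior_theta(prop, prior)
            if not np.isfinite(prop_prior):
                continue
            sp_prop = _sp_from_theta(prop)
            new_pieces = lik.update_pieces(pieces, sp_prop, _BLOCK_OF[k])
            new_loglik = lik.loglik(new_pieces, sp_prop.ptf)
            if np.log(rng.random()) < (new_loglik + prop_prior) - (cur_loglik + cur_prior):
                theta, pieces = prop, new_pieces
                cur_loglik, cur_prior = new_loglik, prop_prior
                accepted[k] = 1.0

        # one correlation-aware joint proposal per sweep
        prop = joint.propose(theta, rng)
        if prop is not None:
            prop_prior = _log_prior_theta(prop, prior)
            if np.isfinite(prop_prior):
                sp_prop = _sp_from_theta(prop)
                new_pieces = lik.pieces(sp_prop)
                new_loglik = lik.loglik(new_pieces, sp_prop.ptf)
                ok = np.log(rng.random()) < (
                    (new_loglik + prop_prior) - (cur_loglik + cur_prior)
                )
                if ok:
                    theta, pieces = prop, new_pieces
                    cur_loglik, cur_prior = new_loglik, prop_prior
                joint.record(bool(ok))
            else:
                joint.record(False)

        if it < settings.n_burnin:
            adapter.record(accepted)
            joint.observe(theta)
            joint.maybe_update()
            if it == settings.n_burnin - 1:
                adapter.frozen = True
                joint.frozen = True
        else:
            accept_totals += accepted
            if (it - settings.n_burnin) % settings.thin == 0:
                draw = theta.copy()
                if with_ptf:
                    draw[6] = special.ndtr(draw[6])  # store P(TF) as probability
                out[kept] = draw
                kept += 1
    post_iters = max(n_iter - settings.n_burnin, 1)
    return out, accept_totals / post_iters, adapter.sds


# --------------------------------------------------------------------------
# hierarchical machinery
# --------------------------------------------------------------------------

_GROUP_RT_IDX = {name: i for i, name in enumerate(RT_PARAMS)}


def _truncnorm_logpdf_vec(x, lo, hi, mean, sd):
    """Vectorized truncated-normal log density (finite-support checked)."""
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    log_mass = np.log(special.ndtr(b) - special.ndtr(a))
    z = (x - mean) / sd
    out = -0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi) - log_mass
    return np.where((x >= lo) & (x <= hi), out, -np.inf)


def _subject_prior_terms(theta, group_means, group_sds, prior: PriorSpec):
    """Log density of one subject's sampled coordinates given the group level."""
    lo, hi = prior.rt_bounds
    total = float(
        np.sum(_truncnorm_logpdf_vec(theta[:6], lo, hi, group_means[:6], group_sds[:6]))
    )
    plo, phi = prior.probit_bounds
    total += float(_truncnorm_logpdf_vec(theta[6], plo, phi, group_means[6], group_sds[6]))
    return total


def _group_block_logp(values_k, k, group_means, group_sds, prior):
    """Sum of subject-level terms for coordinate k plus its hyperprior."""
    if k < 6:
        lo, hi = prior.rt_bounds
        name = RT_PARAMS[k]
        mlo, mhi = prior.group_mean_bounds[name]
        slo, shi = prior.group_sd_bounds[name]
        hyper = 0.0
        if not mlo <= group_means[k] <= mhi:
            return -np.inf
        if not slo <= group_sds[k] <= shi:
            return -np.inf
    else:
        lo, hi = prior.probit_bounds
        slo, shi = prior.group_sd_bounds["ptf"]
        if not lo <= group_means[6] <= hi:
            return -np.inf
        if not slo <= group_sds[6] <= shi:
            return -np.inf
        # standard normal truncated at +-6 on the group mean
        hyper = -0.5 * group_means[6] ** 2
    terms = _truncnorm_logpdf_vec(values_k, lo, hi, group_means[k], group_sds[k])
    return float(np.sum(terms)) + hyper


def _run_hierarchical_chain(liks, prior, settings, rng, theta0s, group0):
    n_subj = len(liks)
    thetas = [t.copy() for t in theta0s]
    g_means = group0[0].copy()
    g_sds = group0[1].copy()

    pieces = []
    logliks = np.empty(n_subj)
    for j, lik in enumerate(liks):
        sp = _sp_from_theta(thetas[j])
        pc = lik.pieces(sp)
        pieces.append(pc)
        logliks[j] = lik.loglik(pc, sp.ptf)

    subj_adapters = [
        _Adapter(_init_proposal_sds(thetas[j], True),
                 settings.adapt_interval, settings.target_accept)
        for j in range(n_subj)
    ]
    subj_joints = [
        _JointAdapter(list(range(7)), settings.adapt_interval)
        for _ in range(n_subj)
    ]
    g_adapter = _Adapter(
        np.r_[np.maximum(0.05 * np.abs(g_means[:6]), 1.0), [0.1],
              np.maximum(0.1 * g_sds[:6], 1.0), [0.05]],
        settings.adapt_interval, settings.target_accept,
    )

    n_par = n_subj * 7 + 14
    n_iter = settings.n_burnin + settings.n_retained * settings.thin
    out = np.empty((settings.n_retained, n_par))
    kept = 0

    subj_mat = np.stack(thetas)  # (n_subj, 7) view kept in sync

    for it in range(n_iter):
        # subject-level blocks
        for j, lik in enumerate(liks):
            theta = thetas[j]
            accepted = np.zeros(7)
            for k in range(7):
                prop = theta.copy()
                prop[k] += subj_adapters[j].sds[k] * rng.standard_normal()
                if k < 6:
                    lo, hi = prior.rt_bounds
                    if not lo <= prop[k] <= hi:
                        continue
                else:
                    plo, phi = prior.probit_bounds
                    if not plo <= prop[k] <= phi:
                        continue
                cur_pr = _one_subject_term(theta[k], k, g_means, g_sds, prior)
                new_pr = _one_subject_term(prop[k], k, g_means, g_sds, prior)
                sp_prop = _sp_from_theta(prop)
                new_pieces = lik.update_pieces(pieces[j], sp_prop, _BLOCK_OF[k])
                new_loglik = lik.loglik(new_pieces, sp_prop.ptf)
                if np.log(rng.random()) < (new_loglik + new_pr) - (logliks[j] + cur_pr):
                    theta[:] = prop
                    pieces[j] = new_pieces
                    logliks[j] = new_loglik
                    accepted[k] = 1.0
            # correlation-aware joint proposal for this subject
            prop = subj_joints[j].propose(theta, rng)
            if prop is not None:
                new_pr = _subject_prior_terms(prop, g_means, g_sds, prior)
                if np.isfinite(new_pr):
                    cur_pr = _subject_prior_terms(theta, g_means, g_sds, prior)
                    sp_prop = _sp_from_theta(prop)
                    new_pieces = lik.pieces(sp_prop)
                    new_loglik = lik.loglik(new_pieces, sp_prop.ptf)
                    ok = np.log(rng.random()) < (
                        (new_loglik + new_pr) - (logliks[j] + cur_pr)
                    )
                    if ok:
                        theta[:] = prop
                        pieces[j] = new_pieces
                        logliks[j] = new_loglik
                    subj_joints[j].record(bool(ok))
                else:
                    subj_joints[j].record(False)

            subj_mat[j] = theta
            if it < settings.n_burnin:
                subj_adapters[j].record(accepted)
                subj_joints[j].observe(theta)
                subj_joints[j].maybe_update()

        # group-level blocks (no likelihood terms)
        g_accepted = np.zeros(14)
        for k in range(7):
            values_k = subj_mat[:, k]
            # location
            prop_means = g_means.copy()
            prop_means[k] += g_adapter.sds[k] * rng.standard_normal()
            cur = _group_block_logp(values_k, k, g_means, g_sds, prior)
            new = _group_block_logp(values_k, k, prop_means, g_sds, prior)
            if np.log(rng.random()) < new - cur:
                g_means = prop_means
                g_accepted[k] = 1.0
            # scale
            prop_sds = g_sds.copy()
            prop_sds[k] += g_adapter.sds[7 + k] * rng.standard_normal()
            if prop_sds[k] > 0:
                cur = _group_block_logp(values_k, k, g_means, g_sds, prior)
                new = _group_block_logp(values_k, k, g_means, prop_sds, prior)
                if np.log(rng.random()) < new - cur:
                    g_sds = prop_sds
                    g_accepted[7 + k] = 1.0
        if it < settings.n_burnin:
            g_adapter.record(g_accepted)
            if it == settings.n_burnin - 1:
                g_adapter.frozen = True
                for a in subj_adapters:
                    a.frozen = True
                for jnt in subj_joints:
                    jnt.frozen = True
        elif (it - settings.n_burnin) % settings.thin == 0:
            row = []
            for j in range(n_subj):
                d = thetas[j].copy()
                d[6] = special.ndtr(d[6])
                row.extend(d)
            row.extend(g_means)
            row.extend(g_sds)
            out[kept] = row
            kept += 1
    return out


def _one_subject_term(value, k, g_means, g_sds, prior):
    if k < 6:
        lo, hi = prior.rt_bounds
    else:
        lo, hi = prior.probit_bounds
    return float(_truncnorm_logpdf_vec(value, lo, hi, g_means[k], g_sds[k]))


def hierarchical_param_names(subject_ids) -> list:
    names = [f"{p}[{sid}]" for sid in subject_ids for p in PARAM_NAMES]
    names += [f"{p}_mean" for p in PARAM_NAMES]
    names += [f"{p}_sd" for p in PARAM_NAMES]
    return names


# --------------------------------------------------------------------------
# public entry point
# --------------------------------------------------------------------------

def fit(data, model: str = "individual", prior: PriorSpec | None = None,
        settings: SamplerSettings | None = None,
        likelihood_settings: LikelihoodSettings | None = None,
        fixed: dict | None = None) -> PosteriorChains:
    """Sample the posterior of an individual, standard, or hierarchical model.

    ``fixed`` (individual/standard only) pins named parameters at given
    natural-scale values; their blocks are skipped, which is useful for
    low-dimensional oracle comparisons.

    Group-level P(TF) entries of hierarchical chains (``ptf_mean``,
    ``ptf_sd``) are reported on the probit scale; subject-level ``ptf`` draws
    are reported as probabilities.
    """
    prior = prior or PriorSpec()
    settings = settings or SamplerSettings()
    lik_settings = likelihood_settings or DEFAULT_SETTINGS
    if len(data) == 0:
        raise ValueError("cannot fit an empty trial table")
    if not data["is_stop"].astype(bool).any():
        raise ValueError("no stop-signal trials: stop parameters are unidentified")

    ss = np.random.SeedSequence(settings.seed)

    if model in ("individual", "standard"):
        if data["subject"].nunique() > 1:
            raise ValueError(f"{model} model expects a single subject")
        lik = _SubjectLik(data, lik_settings)
        with_ptf = model == "individual"
        names = list(PARAM_NAMES if with_ptf else PARAM_NAMES[:6])
        fixed = fixed or {}
        fixed_idx = {}
        for name, value in fixed.items():
            k = names.index(name)
            fixed_idx[k] = float(special.ndtri(value)) if name == "ptf" else float(value)

        chains = []
        accept = []
        prop_sds = []
        for child in ss.spawn(settings.n_chains):
            rng = np.random.default_rng(child)
            theta0 = _moment_init(lik, prior, rng, with_ptf)
            for k, v in fixed_idx.items():
                theta0[k] = v
            draws, acc, sds = _run_individual_chain(
                lik, prior, settings, lik_settings, rng, model, fixed_idx, theta0
            )
            chains.append(draws)
            accept.append(acc)
            prop_sds.append(sds)
        return PosteriorChains(
            draws=np.stack(chains),
            param_names=names,
            model=model,
            n_burnin=settings.n_burnin,
            seed=settings.seed,
            accept_rates={"mean": np.mean(accept, axis=0).tolist()},
            proposal_sds={"per_chain": [s.tolist() for s in prop_sds]},
        )

    if model != "hierarchical":
        raise ValueError(f"unknown model {model!r}")

    subject_ids = sorted(data["subject"].unique())
    liks = [
        _SubjectLik(data[data["subject"] == sid], lik_settings) for sid in subject_ids
    ]
    chains = []
    for child in ss.spawn(settings.n_chains):
        rng = np.random.default_rng(child)
        theta0s = [_moment_init(lik, prior, rng, True) for lik in liks]
        mat = np.stack(theta0s)
        g_means0 = mat.mean(axis=0)
        g_sds0 = np.maximum(mat.std(axis=0, ddof=0), np.r_[np.full(6, 10.0), 0.2])
        g_means0 = _clip_group_means(g_means0, prior)
        chains.append(
            _run_hierarchical_chain(
                liks, prior, settings, rng, theta0s, (g_means0, g_sds0)
            )
        )
    return PosteriorChains(
        draws=np.stack(chains),
        param_names=hierarchical_param_names(subject_ids),
        model="hierarchical",
        n_burnin=settings.n_burnin,
        seed=settings.seed,
    )


def _clip_group_means(g_means, prior: PriorSpec):
    out = g_means.copy()
    for k, name in enumerate(RT_PARAMS):
        lo, hi = prior.group_mean_bounds[name]
        out[k] = np.clip(out[k], lo + 1.0, hi - 1.0)
    plo, phi = prior.probit_bounds
    out[6] = np.clip(out[6], plo + 0.1, phi - 0.1)
    return out
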