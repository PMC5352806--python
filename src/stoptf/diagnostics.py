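"""Model comparison and criticism: DIC, posterior-predictive checks, summaries.

DIC follows the classic Spiegelhalter formulation
``DIC = Dbar + pD`` with ``pD = Dbar - D(theta_bar)``, where ``Dbar`` is the
posterior mean deviance and ``theta_bar`` the posterior mean of the
parameters on their sampling scale (the probit scale for P(TF)).  The
deviance is -2 times the full race-model log-likelihood, go trials included;
for hierarchical fits it conditions on the subject-level parameters (the
"focus" is the subject level).  Smaller DIC = better-supported model; a
difference above 10 is conventionally treated as strong evidence.

Posterior-predictive checks replay the observed SSD sequence at parameter
vectors drawn from the joint posterior and compare observed per-SSD
signal-respond rates with their predictive distributions.  The p value for a
cell is the fraction of predicted rates strictly greater than the observed
rate, except on cells with an observed rate of exactly 1, where it is the
fraction greater than or equal (a strictly-greater count is impossible
there).  Cells with at least ten stop trials form the reported set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .distributions import exgauss_sample
from .likelihood import LikelihoodSettings, total_loglik
from .params import PARAM_NAMES, SubjectParams
from .sampler import PosteriorChains

__all__ = [
    "DICResult",
    "dic",
    "dic_difference",
    "PPCReport",
    "ppc",
    "summarize_posterior",
]

MIN_TRIALS_REPORTED = 10


@dataclass(frozen=True)
class DICResult:
    dic: float
    mean_deviance: float
    p_d: float
    deviance_at_mean: float
    model: str
    n_draws: int
    used_median_fallback: bool = False


def _subject_param_sets(chains: PosteriorChains, data) -> dict:
    """Map subject id -> (n_draws, 7) natural-scale parameter matrix."""
    if chains.model in ("individual", "standard"):
        sid = data["subject"].iloc[0]
        cols = [chains.get(p) for p in PARAM_NAMES[:6]]
        if chains.model == "individual":
            cols.append(chains.get("ptf"))
        else:
            cols.append(np.zeros_like(cols[0]))
        return {sid: np.column_stack(cols)}
    out = {}
    for sid in sorted(data["subject"].unique()):
        cols = [chains.get(f"{p}[{sid}]") for p in PARAM_NAMES]
        out[sid] = np.column_stack(cols)
    return out


def _mean_on_sampling_scale(mat: np.ndarray) -> np.ndarray:
    """Posterior mean with P(TF) averaged on the probit scale."""
    mean = mat.mean(axis=0)
    ptf = np.clip(mat[:, 6], 1e-12, 1 - 1e-12)
    if np.all(mat[:, 6] == 0):
        mean[6] = 0.0
    else:
        mean[6] = float(special.ndtr(np.mean(special.ndtri(ptf))))
    return mean


def _deviance(data_by_subject, param_sets, idx, settings) -> float:
    d = 0.0
    for sid, df in data_by_subject.items():
        sp = SubjectParams.from_vector(param_sets[sid][idx])
        d += -2.0 * total_loglik(df, sp, settings)
    return d


def dic(chains: PosteriorChains, data, settings: LikelihoodSettings | None = None,
        max_draws: int = 1000) -> DICResult:
    """Deviance information criterion for a fitted model.

    ``max_draws`` caps the number of posterior draws used for the mean
    deviance (an evenly-strided subsample; the Monte-Carlo error of Dbar
    shrinks as 1/sqrt(draws)).
    """
    param_sets = _subject_param_sets(chains, data)
    data_by_subject = {
        sid: data[data["subject"] == sid] for sid in param_sets
    }
    n_total = next(iter(param_sets.values())).shape[0]
    stride = max(1, n_total // max_draws)
    idxs = np.arange(0, n_total, stride)

    devs = np.array(
        [_deviance(data_by_subject, param_sets, i, settings) for i in idxs]
    )
    mean_dev = float(np.mean(devs))

    used_median = False
    d_at_mean = 0.0
    for sid, df in data_by_subject.items():
        mean_vec = _mean_on_sampling_scale(param_sets[sid])
        try:
            sp = SubjectParams.from_vector(mean_vec)
        except ValueError:
            sp = SubjectParams.from_vector(np.median(param_sets[sid], axis=0))
            used_median = True
        d_at_mean += -2.0 * total_loglik(df, sp, settings)

    p_d = mean_dev - d_at_mean
    return DICResult(
        dic=mean_dev + p_d,
        mean_deviance=mean_dev,
        p_d=p_d,
        deviance_at_mean=d_at_mean,
        model=chains.model,
        n_draws=len(idxs),
        used_median_fallback=used_median,
    )


def dic_difference(a: DICResult, b: DICResult) -> float:
    """DIC(a) - DIC(b); negative favours model ``a``."""
    return a.dic - b.dic


@dataclass
class PPCReport:
    """Observed-vs-predicted summaries from posterior-predictive replication."""

    rates: pd.DataFrame          # per (subject, ssd): n, observed, p, quantiles
    go_summary: pd.DataFrame     # per subject: observed vs predicted go-RT stats
    n_rep: int
    rate_draws: dict = field(default_factory=dict)  # (subject, ssd) -> predicted rates


def ppc(chains: PosteriorChains, data, n_rep: int = 1000, seed=None) -> PPCReport:
    """Posterior-predictive check replaying the observed SSD sequence."""
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    rng = np.random.default_rng(seed)
    param_sets = _subject_param_sets(chains, data)
    n_total = next(iter(param_sets.values())).shape[0]
    pick = rng.integers(0, n_total, size=n_rep)

    rate_rows = []
    go_rows = []
    rate_draws = {}
    for sid, mat in param_sets.items():
        df = data[data["subject"] == sid]
        is_stop = df["is_stop"].astype(bool)
        go_rts = df.loc[~is_stop, "rt"].to_numpy(float)
        stop = df.loc[is_stop]
        ssds = stop["ssd"].to_numpy(float)
        responded = stop["responded"].astype(bool).to_numpy()
        uniq, inverse, counts = np.unique(ssds, return_inverse=True, return_counts=True)
        obs_rate = np.bincount(inverse, weights=responded) / counts
        n_stop = len(ssds)

        pred_rates = np.empty((n_rep, len(uniq)))
        pred_go_mean = np.empty(n_rep)
        pred_go_sd = np.empty(n_rep)
        for r, i in enumerate(pick):
            sp = SubjectParams.from_vector(mat[i])
            go = exgauss_sample(max(len(go_rts), 1), sp.go, rng)
            pred_go_mean[r] = go.mean()
            pred_go_sd[r] = go.std()
            trial_go = exgauss_sample(n_stop, sp.go, rng)
            trig = rng.random(n_stop) >= sp.ptf
            ssrt = exgauss_sample(n_stop, sp.stop, rng)
            resp = ~trig | (trial_go < ssds + ssrt)
            pred_rates[r] = np.bincount(inverse, weights=resp, minlength=len(uniq)) / counts

        for j, s in enumerate(uniq):
            obs = obs_rate[j]
            if obs >= 1.0:
                p = float(np.mean(pred_rates[:, j] >= obs))
            else:
                p = float(np.mean(pred_rates[:, j] > obs))
            lo, med, hi = np.percentile(pred_rates[:, j], [2.5, 50, 97.5])
            rate_rows.append(
                {"subject": sid, "ssd": s, "n_trials": int(counts[j]),
                 "observed_rate": obs, "p": p,
                 "pred_median": med, "pred_lo": lo, "pred_hi": hi,
                 "reported": counts[j] >= MIN_TRIALS_REPORTED}
            )
            rate_draws[(sid, float(s))] = pred_rates[:, j].copy()
        if len(go_rts):
            go_rows.append(
                {"subject": sid,
                 "observed_mean": float(go_rts.mean()),
                 "observed_sd": float(go_rts.std()),
                 "pred_mean_lo": float(np.percentile(pred_go_mean, 2.5)),
                 "pred_mean_hi": float(np.percentile(pred_go_mean, 97.5)),
                 "pred_sd_lo": float(np.percentile(pred_go_sd, 2.5)),
                 "pred_sd_hi": float(np.percentile(pred_go_sd, 97.5))}
            )
    return PPCReport(
        rates=pd.DataFrame(rate_rows),
        go_summary=pd.DataFrame(go_rows),
        n_rep=n_rep,
        rate_draws=rate_draws,
    )


def summarize_posterior(chains: PosteriorChains) -> pd.DataFrame:
    """Posterior medians with central 95% credible intervals."""
    rows = []
    for name in chains.param_names:
        x = chains.get(name)
        lo, med, hi = np.percentile(x, [2.5, 50, 97.5])
        rows.append({"parameter": name, "median": med, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def plot_go_ppc(report: PPCReport, data, subject, ax=None, bins: int = 30):
    """Histogram of observed go RTs with predictive mean band annotations."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    df = data[(data["subject"] == subject) & (~data["is_stop"].astype(bool))]
    ax.hist(df["rt"], bins=bins, density=True, color="0.8", edgecolor="0.5")
    row = report.go_summary[report.go_summary["subject"] == subject].iloc[0]
    ax.axvline(row["observed_mean"], color="k", label="observed mean")
    ax.axvspan(row["pred_mean_lo"], row["pred_mean_hi"], alpha=0.3,
               label="95% predictive (mean)")
    ax.set_xlabel("go RT (ms)")
    ax.legend()
    return ax


def plot_inhibition_ppc(report: PPCReport, subject, ax=None):
    """Violin-style predictive signal-respond rates per SSD vs the observed rates."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sub = report.rates[report.rates["subject"] == subject].sort_values("ssd")
    draws = [report.rate_draws[(subject, float(s))] for s in sub["ssd"]]
    ax.violinplot(draws, positions=sub["ssd"], widths=0.8 * np.diff(
        np.r_[sub["ssd"].to_numpy(), sub["ssd"].to_numpy()[-1] + 50]).min())
    ax.plot(sub["ssd"], sub["observed_rate"], "k--o", label="observed")
    ax.set_xlabel("SSD (ms)")
    ax.set_ylabel("signal-respond rate")
    ax.legend()
    return ax
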