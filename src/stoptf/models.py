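"""Model definitions: priors, transforms, and log-posterior assembly.

Three model variants share the race likelihood:

* ``individual`` — one participant, seven free parameters (go triple, stop
  triple, trigger-failure probability P(TF));
* ``standard`` — the same race model with P(TF) pinned at zero (the classic
  censored-distribution formulation); it is the exact nested restriction of
  the trigger-failure model;
* ``hierarchical`` — subject-level parameters drawn from truncated-normal
  group distributions ([0, 1000] ms for the six RT parameters; a +-6
  truncated normal on the probit scale for P(TF)).

Individual-level priors are weakly informative uniforms; the group-level
location of P(TF) carries a standard-normal prior truncated at +-6 and all
other hyperparameters carry wide uniforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .distributions import probit_inv, truncnorm_logpdf
from .likelihood import LikelihoodSettings, total_loglik
from .params import PARAM_NAMES, GroupParams, SubjectParams

__all__ = [
    "PriorSpec",
    "default_prior",
    "log_prior_individual",
    "log_prior_hierarchical",
    "log_posterior",
    "MODELS",
]

MODELS = ("individual", "standard", "hierarchical")

RT_PARAMS = PARAM_NAMES[:6]


@dataclass(frozen=True)
class PriorSpec:
    """Uniform bounds for subject-level parameters and group hyperparameters.

    ``bounds`` maps each subject-level parameter to its uniform support
    (P(TF) on the probability scale).  ``group_mean_bounds`` and
    ``group_sd_bounds`` play the same role for the hierarchical hyperpriors,
    except the group-level mean of P(TF), which has a standard-normal prior
    truncated at ``probit_bounds``.  Subject-level truncation bounds for the
    hierarchical model are ``rt_bounds`` / ``probit_bounds``.
    """

    bounds: dict = field(default_factory=lambda: {
        "mu_go": (1.0, 1000.0),
        "sigma_go": (1.0, 500.0),
        "tau_go": (1.0, 500.0),
        "mu_stop": (1.0, 1000.0),
        "sigma_stop": (1.0, 500.0),
        "tau_stop": (1.0, 500.0),
        "ptf": (0.0, 1.0),
    })
    group_mean_bounds: dict = field(default_factory=lambda: {
        "mu_go": (1.0, 1000.0),
        "sigma_go": (1.0, 500.0),
        "tau_go": (1.0, 500.0),
        "mu_stop": (1.0, 1000.0),
        "sigma_stop": (1.0, 500.0),
        "tau_stop": (1.0, 500.0),
    })
    group_sd_bounds: dict = field(default_factory=lambda: {
        **{n: (0.01, 500.0) for n in RT_PARAMS},
        "ptf": (0.01, 3.0),
    })
    rt_bounds: tuple = (0.0, 1000.0)
    probit_bounds: tuple = (-6.0, 6.0)

    def to_dict(self) -> dict:
        return {
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "group_mean_bounds": {k: list(v) for k, v in self.group_mean_bounds.items()},
            "group_sd_bounds": {k: list(v) for k, v in self.group_sd_bounds.items()},
            "rt_bounds": list(self.rt_bounds),
            "probit_bounds": list(self.probit_bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        base = cls()
        kwargs = {}
        for key in ("bounds", "group_mean_bounds", "group_sd_bounds"):
            if key in d:
                merged = {**getattr(base, key), **{k: tuple(v) for k, v in d[key].items()}}
                kwargs[key] = merged
        for key in ("rt_bounds", "probit_bounds"):
            if key in d:
                kwargs[key] = tuple(d[key])
        return replace(base, **kwargs)


def default_prior() -> PriorSpec:
    return PriorSpec()


def _log_uniform(x: float, lo: float, hi: float) -> float:
    return -np.log(hi - lo) if lo <= x <= hi else -np.inf


def log_prior_individual(sp: SubjectParams, prior: PriorSpec | None = None) -> float:
    """Log prior density of one participant's parameters (natural scale)."""
    prior = prior or PriorSpec()
    total = 0.0
    for name, value in zip(PARAM_NAMES, sp.to_vector()):
        total += _log_uniform(value, *prior.bounds[name])
        if not np.isfinite(total):
            return -np.inf
    return total


def log_prior_hierarchical(gp: GroupParams, subjects: list[SubjectParams],
                           prior: PriorSpec | None = None) -> float:
    """Hyperprior plus truncated-normal subject-level terms.

    The six RT parameters contribute truncated-normal log densities on
    [0, 1000] ms; P(TF) contributes on the probit scale (its subject-level
    values are mapped through the probit before evaluating the +-6 truncated
    normal).
    """
    prior = prior or PriorSpec()
    total = 0.0
    for name in RT_PARAMS:
        total += _log_uniform(gp.means[name], *prior.group_mean_bounds[name])
        total += _log_uniform(gp.sds[name], *prior.group_sd_bounds[name])
    # standard normal truncated at +-6 for the probit-scale P(TF) location
    total += float(
        truncnorm_logpdf(gp.means["ptf"], *prior.probit_bounds, 0.0, 1.0)
    )
    total += _log_uniform(gp.sds["ptf"], *prior.group_sd_bounds["ptf"])
    if not np.isfinite(total):
        return -np.inf

    from .distributions import probit  # local import to avoid cycle at module load

    lo, hi = prior.rt_bounds
    for sp in subjects:
        vec = sp.to_vector()
        for name, value in zip(RT_PARAMS, vec[:6]):
            total += float(
                truncnorm_logpdf(value, lo, hi, gp.means[name], gp.sds[name])
            )
        z = float(probit(np.clip(sp.ptf, 1e-12, 1 - 1e-12)))
        total += float(
            truncnorm_logpdf(z, *prior.probit_bounds, gp.means["ptf"], gp.sds["ptf"])
        )
        if not np.isfinite(total):
            return -np.inf
    return total


def _pin_standard(sp: SubjectParams) -> SubjectParams:
    return SubjectParams(go=sp.go, stop=sp.stop, ptf=0.0)


def log_posterior(model: str, data, params, prior: PriorSpec | None = None,
                  settings: LikelihoodSettings | None = None) -> float:
    """Log posterior density (up to a constant) for any model variant.

    ``params`` is a :class:`SubjectParams` for the individual and standard
    models, or a ``(GroupParams, list[SubjectParams])`` pair for the
    hierarchical model (subject order must match the sorted subject ids in
    ``data``).
    """
    prior = prior or PriorSpec()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")

    if model in ("individual", "standard"):
        sp = params
        if model == "standard":
            sp = _pin_standard(sp)
            lp = log_prior_individual(sp, prior) - _log_uniform(0.0, *prior.bounds["ptf"])
        else:
            lp = log_prior_individual(sp, prior)
        if not np.isfinite(lp):
            return -np.inf
        if data is None or len(data) == 0:
            return lp
        return lp + total_loglik(data, sp, settings)

    gp, subjects = params
    lp = log_prior_hierarchical(gp, subjects, prior)
    if not np.isfinite(lp):
        return -np.inf
    if data is None or len(data) == 0:
        return lp
    for subj_id, sp in zip(sorted(data["subject"].unique()), subjects):
        lp += total_loglik(data[data["subject"] == subj_id], sp, settings)
    return lp
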