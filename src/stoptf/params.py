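"""Parameter containers for one participant and for the group level."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import ExGaussParams, probit, probit_inv

__all__ = ["SubjectParams", "GroupParams", "PARAM_NAMES", "GROUP_PARAM_NAMES"]

#: canonical parameter order used throughout the sampler and chain output;
#: ``ptf`` is carried on the probit scale inside the sampler ("z_tf")
PARAM_NAMES = ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop", "ptf")

GROUP_PARAM_NAMES = tuple(f"{n}_{s}" for n in PARAM_NAMES for s in ("mean", "sd"))


@dataclass(frozen=True)
class SubjectParams:
    """Go and stop ex-Gaussian triples plus the trigger-failure probability.

    ``ptf`` is the probability that the stop process is never launched on a
    stop-signal trial, in which case no race takes place and the response
    follows the unconditional go-RT distribution.
    """

    go: ExGaussParams
    stop: ExGaussParams
    ptf: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ptf <= 1.0):
            raise ValueError(f"ptf must lie in [0, 1], got {self.ptf}")

    def to_vector(self) -> np.ndarray:
        """Natural-scale vector in :data:`PARAM_NAMES` order."""
        return np.array(
            [self.go.mu, self.go.sigma, self.go.tau,
             self.stop.mu, self.stop.sigma, self.stop.tau, self.ptf]
        )

    @classmethod
    def from_vector(cls, v) -> "SubjectParams":
        v = np.asarray(v, dtype=float)
        return cls(go=ExGaussParams(*v[:3]), stop=ExGaussParams(*v[3:6]), ptf=float(v[6]))

    @property
    def mean_ssrt(self) -> float:
        return self.stop.mean


@dataclass(frozen=True)
class GroupParams:
    """Group-level means and SDs of the seven subject-level parameters.

    The six RT parameters live on the millisecond scale (their subject-level
    distributions are normals truncated to [0, 1000] ms).  The trigger-failure
    probability is modelled on the probit scale: ``ptf_mean`` / ``ptf_sd``
    parameterise a normal truncated at +-6 whose inverse-probit image is the
    subject-level P(TF).
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    # truncation bounds applied to the subject-level distributions
    rt_bounds: tuple = (0.0, 1000.0)
    probit_bounds: tuple = (-6.0, 6.0)

    def __post_init__(self) -> None:
        missing = [n for n in PARAM_NAMES if n not in self.means or n not in self.sds]
        if missing:
            raise ValueError(f"GroupParams missing entries for {missing}")
        bad = [n for n in PARAM_NAMES if not self.sds[n] > 0]
        if bad:
            raise ValueError(f"group SDs must be > 0 ({bad})")
        lo, hi = self.probit_bounds
        if not lo <= self.means["ptf"] <= hi:
            raise ValueError("probit-scale P(TF) mean outside truncation bounds")

    @classmethod
    def from_values(cls, ptf_mean_probability: bool = False, **kwargs) -> "GroupParams":
        """Build from ``<name>_mean`` / ``<name>_sd`` keyword pairs.

        ``ptf_mean`` is interpreted on the probit scale unless
        ``ptf_mean_probability=True``, in which case it is probit-transformed.
        """
        means = {n: float(kwargs.pop(f"{n}_mean")) for n in PARAM_NAMES}
        sds = {n: float(kwargs.pop(f"{n}_sd")) for n in PARAM_NAMES}
        if kwargs:
            raise TypeError(f"unexpected arguments: {sorted(kwargs)}")
        if ptf_mean_probability:
            means["ptf"] = float(probit(means["ptf"]))
        return cls(means=means, sds=sds)

    def to_vector(self) -> np.ndarray:
        return np.array(
            [v for n in PARAM_NAMES for v in (self.means[n], self.sds[n])]
        )

    @property
    def ptf_mean_probability(self) -> float:
        """Group-level P(TF) location mapped back to the probability scale."""
        return float(probit_inv(self.means["ptf"]))
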