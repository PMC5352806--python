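"""Race-model simulator for stop-signal experiments.

Generates trial-level data from the trigger-failure race model: on each
stop-signal trial the stop process either fails to launch (probability
``ptf``, leaving the go process unopposed) or races the go process from
stop-signal onset.  A response is emitted iff the go finishing time beats
SSD + SSRT.  Both the classic fixed-SSD design and the one-up/one-down
staircase that tracks a 0.50 signal-respond rate are supported, plus a
relative-SSD mode in which stop signals are yoked to the running mean go RT.

Trial tables are tidy pandas DataFrames with columns ``subject``,
``is_stop``, ``ssd``, ``responded``, ``rt``; missing entries (ssd on go
trials, rt on successful inhibitions) are NaN.  All times share one origin:
RTs and SSDs are measured from go-stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import exgauss_sample, probit_inv, truncnorm_sample
from .params import PARAM_NAMES, GroupParams, SubjectParams

__all__ = [
    "SSDSchedule",
    "SubjectParams",
    "simulate_stop_trial",
    "simulate_dataset",
    "simulate_hierarchical",
    "staircase_update",
    "validate_trial_table",
]

TRIAL_COLUMNS = ["subject", "is_stop", "ssd", "responded", "rt"]


@dataclass(frozen=True)
class SSDSchedule:
    """How stop-signal delays are assigned across the stop trials.

    fixed
        ``fixed_levels`` maps SSD (ms) -> number of stop trials at that delay;
        a plain list of delays splits the requested stop count evenly.
    staircase
        one-up/one-down tracking: SSD decreases by ``step`` after a response
        and increases by ``step`` after an inhibition, clamped to
        ``[lo, hi]``; this drives the signal-respond rate toward 0.50.
    relative
        stop signals are presented at fixed offsets (ms) *before* the current
        mean of the go RTs simulated so far, cycling through ``offsets``.
    """

    mode: str = "staircase"
    fixed_levels: dict | list | None = None
    start_ssd: float = 200.0
    step: float = 50.0
    lo: float = 0.0
    hi: float = 1000.0
    offsets: tuple = (500.0, 400.0, 300.0, 200.0, 100.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "staircase", "relative"):
            raise ValueError(f"unknown SSD schedule mode {self.mode!r}")
        if self.mode == "fixed":
            if not self.fixed_levels:
                raise ValueError("fixed mode requires at least one SSD level")
        if self.mode == "staircase" and not self.step > 0:
            raise ValueError("staircase step must be > 0")

    def level_counts(self, n_stop: int) -> list[tuple[float, int]]:
        """Resolve fixed levels to (ssd, count) pairs summing to ``n_stop``."""
        if isinstance(self.fixed_levels, dict):
            return [(float(s), int(c)) for s, c in self.fixed_levels.items()]
        levels = list(self.fixed_levels)
        base, extra = divmod(n_stop, len(levels))
        return [
            (float(s), base + (1 if i < extra else 0)) for i, s in enumerate(levels)
        ]


def staircase_update(ssd: float, responded: bool, sched: SSDSchedule) -> float:
    """One-up/one-down tracking step: harder after inhibition, easier after a response."""
    ssd = ssd - sched.step if responded else ssd + sched.step
    return float(min(max(ssd, sched.lo), sched.hi))


def simulate_stop_trial(sp: SubjectParams, ssd: float, rng) -> tuple[bool, float | None]:
    """Simulate one stop-signal trial; returns ``(responded, rt_or_None)``."""
    rng = np.random.default_rng(rng)
    go_rt = float(exgauss_sample(1, sp.go, rng)[0])
    if rng.random() < sp.ptf:
        return True, go_rt  # stop process never triggered: unopposed go
    ssrt = float(exgauss_sample(1, sp.stop, rng)[0])
    if go_rt < ssd + ssrt:
        return True, go_rt
    return False, None


def _stop_trials(sp: SubjectParams, n_stop: int, sched: SSDSchedule, rng,
                 go_rts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector of (ssd, responded, rt) for the stop trials of one subject."""
    ssds = np.empty(n_stop)
    responded = np.empty(n_stop, dtype=bool)
    rts = np.full(n_stop, np.nan)

    if sched.mode == "fixed":
        seq = np.concatenate(
            [np.full(c, s) for s, c in sched.level_counts(n_stop)]
        )
        if len(seq) != n_stop:
            raise ValueError(
                f"fixed-level counts sum to {len(seq)}, expected {n_stop}"
            )
        rng.shuffle(seq)
        go = exgauss_sample(n_stop, sp.go, rng) if n_stop else np.empty(0)
        trig = rng.random(n_stop) >= sp.ptf
        ssrt = exgauss_sample(n_stop, sp.stop, rng) if n_stop else np.empty(0)
        resp = ~trig | (go < seq + ssrt)
        ssds, responded = seq, resp
        rts[resp] = go[resp]
        return ssds, responded, rts

    mean_go = float(np.mean(go_rts)) if len(go_rts) else sp.go.mean
    ssd = sched.start_ssd
    for i in range(n_stop):
        if sched.mode == "relative":
            ssd = max(mean_go - sched.offsets[i % len(sched.offsets)], 0.0)
        resp, rt = simulate_stop_trial(sp, ssd, rng)
        ssds[i], responded[i] = ssd, resp
        if resp:
            rts[i] = rt
        if sched.mode == "staircase":
            ssd = staircase_update(ssd, resp, sched)
    return ssds, responded, rts


def simulate_dataset(sp: SubjectParams, n_go: int, n_stop: int,
                     sched: SSDSchedule | None = None, seed=None,
                     subject: int = 1) -> pd.DataFrame:
    """Simulate one participant's session as a tidy trial table."""
    if n_go < 0 or n_stop < 0:
        raise ValueError("trial counts must be >= 0")
    sched = sched or SSDSchedule()
    rng = np.random.default_rng(seed)

    go_rts = exgauss_sample(n_go, sp.go, rng) if n_go else np.empty(0)
    ssds, responded, stop_rts = _stop_trials(sp, n_stop, sched, rng, go_rts)

    df = pd.DataFrame(
        {
            "subject": subject,
            "is_stop": np.r_[np.zeros(n_go, dtype=bool), np.ones(n_stop, dtype=bool)],
            "ssd": np.r_[np.full(n_go, np.nan), ssds],
            "responded": np.r_[np.ones(n_go, dtype=bool), responded],
            "rt": np.r_[go_rts, stop_rts],
        }
    )
    return df


def draw_subject_params(gp: GroupParams, n_subj: int, rng) -> list[SubjectParams]:
    """Draw participant-level parameters from the group-level distributions.

    RT parameters come from normals truncated to ``gp.rt_bounds`` (default
    [0, 1000] ms); the probit-scale P(TF) from a normal truncated at +-6,
    mapped back through the inverse probit.
    """
    rng = np.random.default_rng(rng)
    draws = {}
    for name in PARAM_NAMES:
        lo, hi = gp.probit_bounds if name == "ptf" else gp.rt_bounds
        draws[name] = truncnorm_sample(
            n_subj, lo, hi, gp.means[name], gp.sds[name], rng
        )
    out = []
    for i in range(n_subj):
        vec = [draws[n][i] for n in PARAM_NAMES[:6]]
        ptf = float(probit_inv(draws["ptf"][i]))
        out.append(SubjectParams.from_vector(vec + [ptf]))
    return out


def simulate_hierarchical(gp: GroupParams, n_subj: int, n_go: int, n_stop: int,
                          sched: SSDSchedule | None = None, seed=None
                          ) -> tuple[pd.DataFrame, list[SubjectParams]]:
    """Simulate a group study; returns the pooled trial table and true params."""
    rng = np.random.default_rng(seed)
    subjects = draw_subject_params(gp, n_subj, rng)
    tables = [
        simulate_dataset(sp, n_go, n_stop, sched, seed=rng, subject=i + 1)
        for i, sp in enumerate(subjects)
    ]
    df = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=TRIAL_COLUMNS)
    return df, subjects


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a trial table; returns ``df``."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    go = df[~df["is_stop"].astype(bool)]
    stop = df[df["is_stop"].astype(bool)]
    if go["rt"].isna().any() or go["ssd"].notna().any():
        raise ValueError("go trials must have an rt and no ssd")
    if not go["responded"].astype(bool).all():
        raise ValueError("go trials must be responses")
    if stop["ssd"].isna().any():
        raise ValueError("stop trials must have an ssd")
    sr = stop[stop["responded"].astype(bool)]
    inh = stop[~stop["responded"].astype(bool)]
    if sr["rt"].isna().any():
        raise ValueError("signal-respond trials must have an rt")
    if inh["rt"].notna().any():
        raise ValueError("inhibition trials must not have an rt")
    if (df["rt"].dropna() <= 0).any():
        raise ValueError("RTs must be positive")
    return df
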