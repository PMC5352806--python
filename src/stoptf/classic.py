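"""Traditional SSRT point estimators.

Two non-parametric estimators serve as the comparison baseline for the
Bayesian race-model fits:

* the **mean method** (typical with staircase tracking, which drives the
  signal-respond rate to 0.50): SSRT = mean go RT - mean SSD;
* the **integration method** (typical with fixed delays): the go-RT
  distribution is "integrated up to" the signal-respond rate — SSRT is the
  go-RT quantile at the observed response rate minus the SSD.

Neither accounts for trigger failures: a trigger failure inflates the
signal-respond rate without any contribution of the stop process, so both
estimators overestimate SSRT increasingly with P(TF).

Quantile convention: empirical quantile by linear interpolation between
order statistics (numpy's default ``"linear"`` method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassicEstimate",
    "ssrt_mean_method",
    "ssrt_integration_method",
    "classic_from_table",
]


@dataclass(frozen=True)
class ClassicEstimate:
    ssrt: float
    method: str
    inputs: dict = field(default_factory=dict)
    excluded_levels: list = field(default_factory=list)


def ssrt_mean_method(go_rts, stop_ssds) -> ClassicEstimate:
    """SSRT = mean go RT - mean SSD over all stop trials."""
    go_rts = np.asarray(go_rts, dtype=float)
    stop_ssds = np.asarray(stop_ssds, dtype=float)
    if go_rts.size == 0 or stop_ssds.size == 0:
        raise ValueError("mean method needs go RTs and stop-trial SSDs")
    mean_go = float(np.mean(go_rts))
    mean_ssd = float(np.mean(stop_ssds))
    return ClassicEstimate(
        ssrt=mean_go - mean_ssd,
        method="mean",
        inputs={"mean_go": mean_go, "mean_ssd": mean_ssd,
                "n_go": int(go_rts.size), "n_stop": int(stop_ssds.size)},
    )


def ssrt_integration_method(go_rts, ssd_levels, pooled: bool = True) -> ClassicEstimate:
    """Go-RT quantile at the signal-respond rate minus the SSD.

    ``ssd_levels`` is a list of ``(ssd, n_trials, respond_rate)`` triples.
    By default rates and SSDs are pooled across levels weighted by trial
    count; ``pooled=False`` estimates per level and averages (levels with
    rate 0 or 1 are excluded and flagged, since the quantile is degenerate
    there).
    """
    go_rts = np.sort(np.asarray(go_rts, dtype=float))
    if go_rts.size == 0 or not ssd_levels:
        raise ValueError("integration method needs go RTs and SSD levels")
    levels = [(float(s), int(n), float(r)) for s, n, r in ssd_levels]
    for _, _, r in levels:
        if not 0.0 <= r <= 1.0:
            raise ValueError("respond rates must lie in [0, 1]")

    if pooled:
        n_tot = sum(n for _, n, _ in levels)
        rate = sum(n * r for _, n, r in levels) / n_tot
        mean_ssd = sum(n * s for s, n, _ in levels) / n_tot
        if rate in (0.0, 1.0):
            raise ValueError("pooled respond rate of 0 or 1: quantile undefined")
        ssrt = float(np.quantile(go_rts, rate, method="linear")) - mean_ssd
        return ClassicEstimate(
            ssrt=ssrt, method="integration",
            inputs={"pooled_rate": rate, "mean_ssd": mean_ssd, "n_stop": n_tot},
        )

    estimates, weights, excluded = [], [], []
    for s, n, r in levels:
        if r in (0.0, 1.0):
            excluded.append(s)
            continue
        estimates.append(float(np.quantile(go_rts, r, method="linear")) - s)
        weights.append(n)
    if not estimates:
        raise ValueError("all SSD levels have degenerate respond rates")
    ssrt = float(np.average(estimates, weights=weights))
    return ClassicEstimate(
        ssrt=ssrt, method="integration",
        inputs={"n_levels": len(estimates)}, excluded_levels=excluded,
    )


def classic_from_table(df: pd.DataFrame, method: str, pooled: bool = True) -> ClassicEstimate:
    """Apply either estimator to a single-subject trial table."""
    is_stop = df["is_stop"].astype(bool)
    go_rts = df.loc[~is_stop, "rt"].to_numpy(float)
    stop = df.loc[is_stop]
    if method == "mean":
        return ssrt_mean_method(go_rts, stop["ssd"].to_numpy(float))
    if method == "integration":
        grouped = stop.groupby("ssd")["responded"].agg(["size", "mean"])
        levels = [(s, int(row["size"]), float(row["mean"]))
                  for s, row in grouped.iterrows()]
        return ssrt_integration_method(go_rts, levels, pooled=pooled)
    raise ValueError(f"unknown method {method!r}")
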