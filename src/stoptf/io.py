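"""Trial-table readers/writers, preprocessing rules, and run configuration.

The on-disk dialect is the BEESTS CSV layout: columns ``subj_idx``,
``ss_presented`` (0/1), ``inhibited`` (1 = successful inhibition, 0 =
signal-respond, -999 on go trials), ``ssd`` (ms, -999 on go trials) and
``rt`` (ms, -999 on successful inhibitions).  Internally tables are tidy
DataFrames with NaN for structurally missing values (see
:mod:`stoptf.simulate`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import TRIAL_COLUMNS, validate_trial_table

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "preprocess",
    "RunConfig",
    "SENTINEL",
]

SENTINEL = -999


def read_trial_table(path) -> pd.DataFrame:
    """Read a BEESTS-dialect CSV into a validated tidy trial table."""
    raw = pd.read_csv(path)
    required = ["subj_idx", "ss_presented", "inhibited", "ssd", "rt"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    is_stop = raw["ss_presented"].astype(int) == 1
    inhibited = raw["inhibited"].astype(int)
    ssd = raw["ssd"].astype(float)
    rt = raw["rt"].astype(float)

    for i, row in enumerate(raw.itertuples(index=False), start=2):  # header = line 1
        stop = int(row.ss_presented) == 1
        if not stop:
            if int(row.inhibited) != SENTINEL or float(row.ssd) != SENTINEL:
                raise ValueError(
                    f"{path}, line {i}: go trial must carry sentinel inhibited/ssd"
                )
            if float(row.rt) == SENTINEL or float(row.rt) <= 0:
                raise ValueError(f"{path}, line {i}: go trial must have a positive rt")
        else:
            if float(row.ssd) == SENTINEL:
                raise ValueError(f"{path}, line {i}: stop trial must have an ssd")
            if int(row.inhibited) == 1 and float(row.rt) != SENTINEL:
                raise ValueError(
                    f"{path}, line {i}: inhibited trial cannot have an rt"
                )
            if int(row.inhibited) == 0 and (
                float(row.rt) == SENTINEL or float(row.rt) <= 0
            ):
                raise ValueError(
                    f"{path}, line {i}: signal-respond trial must have a positive rt"
                )
            if int(row.inhibited) not in (0, 1):
                raise ValueError(f"{path}, line {i}: inhibited must be 0 or 1")

    df = pd.DataFrame(
        {
            "subject": raw["subj_idx"].astype(int),
            "is_stop": is_stop,
            "ssd": ssd.where(is_stop, np.nan),
            "responded": np.where(is_stop, inhibited == 0, True),
            "rt": rt.where(rt != SENTINEL, np.nan),
        }
    )
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a tidy trial table in the BEESTS CSV dialect."""
    validate_trial_table(df)
    is_stop = df["is_stop"].astype(bool)
    responded = df["responded"].astype(bool)
    out = pd.DataFrame(
        {
            "subj_idx": df["subject"].astype(int),
            "ss_presented": is_stop.astype(int),
            "inhibited": np.where(is_stop, (~responded).astype(int), SENTINEL),
            "ssd": df["ssd"].fillna(SENTINEL),
            "rt": df["rt"].fillna(SENTINEL),
        }
    )
    out.to_csv(path, index=False)


def preprocess(df: pd.DataFrame, trim_go_sd: float | None = None,
               sr_rt_floor: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Optional trial-exclusion rules; both are off unless given.

    ``trim_go_sd`` removes each participant's go RTs outside mean +- k * SD
    (computed per subject).  ``sr_rt_floor`` removes signal-respond RTs
    *strictly faster than* the floor (a boundary RT equal to the floor is
    kept).  Returns the filtered table and an exclusion report.
    """
    validate_trial_table(df)
    keep = np.ones(len(df), dtype=bool)
    report = {"n_input": len(df), "go_trimmed": 0, "sr_removed": 0}
    is_stop = df["is_stop"].astype(bool).to_numpy()
    responded = df["responded"].astype(bool).to_numpy()
    rt = df["rt"].to_numpy(float)

    if trim_go_sd is not None:
        for sid, sub in df.groupby("subject"):
            go_mask = (df["subject"] == sid).to_numpy() & ~is_stop
            go_rt = rt[go_mask]
            m, sd = go_rt.mean(), go_rt.std(ddof=0)
            bad = go_mask & ((rt < m - trim_go_sd * sd) | (rt > m + trim_go_sd * sd))
            report["go_trimmed"] += int(bad.sum())
            keep &= ~bad

    if sr_rt_floor is not None:
        bad = is_stop & responded & (rt < sr_rt_floor)
        report["sr_removed"] = int(bad.sum())
        keep &= ~bad

    out = df.loc[keep].reset_index(drop=True)
    report["n_output"] = len(out)
    for sid in df["subject"].unique():
        if not (out["subject"] == sid).any():
            raise ValueError(f"preprocessing removed every trial of subject {sid}")
    return out, report


@dataclass
class RunConfig:
    """Serializable description of one simulation or estimation run."""

    model: str = "individual"
    seed: int | None = None
    prior: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    likelihood: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def manifest(self) -> str:
        import stoptf

        info = asdict(self)
        info["stoptf_version"] = stoptf.__version__
        info["numpy_version"] = np.__version__
        return json.dumps(info, indent=2, default=str)
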