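"""Negative-geotaxis scoring: percentage of flies climbing 5 cm within 5 s.

Each trial records how many of a vial's flies crossed the 5 cm line 5 s
after being knocked down.  A group's score is the mean over its trials; the
genotype summary is mean ± SEM over group scores (the group is the unit of
replication by default, switchable to pooled trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeotaxisTrial", "score_trial", "aggregate", "read_trials", "write_trials"]

_COLS = ["genotype", "group", "trial", "n_flies", "n_climbed"]


@dataclass(frozen=True)
class GeotaxisTrial:
    genotype: str
    group: int
    trial: int
    n_flies: int
    n_climbed: int

    def __post_init__(self):
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if not (0 <= self.n_climbed <= self.n_flies):
            raise ValueError("n_climbed must be in [0, n_flies]")


def score_trial(trial: GeotaxisTrial) -> float:
    """Climbing score of one trial, in percent."""
    return 100.0 * trial.n_climbed / trial.n_flies


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["n_flies"] <= 0).any() or (df["n_climbed"] < 0).any() or \
            (df["n_climbed"] > df["n_flies"]).any():
        raise ValueError(f"{path}: invalid trial counts")
    return df[_COLS]


def write_trials(df: pd.DataFrame, path) -> None:
    df[_COLS].to_csv(path, index=False)


def aggregate(trials: pd.DataFrame, scheme: str = "group") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group scores and genotype summaries from a trial table.

    ``scheme="group"`` (default): each group's score is the mean over its
    trials and the genotype SEM is over group scores (n = number of groups).
    ``scheme="pooled"``: every trial is a replicate.
    Returns ``(group_scores, genotype_summary)``.
    """
    if scheme not in ("group", "pooled"):
        raise ValueError("scheme must be 'group' or 'pooled'")
    t = trials.copy()
    t["score_pct"] = 100.0 * t["n_climbed"] / t["n_flies"]
    group_scores = (
        t.groupby(["genotype", "group"], sort=True)["score_pct"].mean().reset_index()
    )
    unit = group_scores if scheme == "group" else t[["genotype", "score_pct"]]
    summary = (
        unit.groupby("genotype", sort=True)["score_pct"]
        .agg(mean_pct="mean",
             sem_pct=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
             n_units="size")
        .reset_index()
    )
    return group_scores, summary
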