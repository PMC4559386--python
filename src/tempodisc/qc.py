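"""Catch-trial scoring and participant exclusion.

Catch trials have a logically dominant option: 0 euros sooner versus 20 euros
later (the later option dominates) or 20 euros sooner versus 20 euros later
(the sooner option dominates, since waiting adds nothing). A participant is
excluded when more than half of their catch trials are answered against the
dominant option — with the 24 catch trials of the full design that means 13
or more incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class QcReport:
    participant_id: object
    n_catch: int
    n_catch_incorrect: int
    excluded: bool


def score_catch_trials(trials: pd.DataFrame) -> QcReport:
    """Score the catch trials of one participant's trial table."""
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("score_catch_trials expects one participant's trials")
    catch = trials[trials["is_catch"]]
    if catch["choice"].isna().any():
        raise ValueError(f"participant {pids[0]}: missing choice on a catch trial")
    zero_sooner = catch["sooner_amount"] == 0.0
    correct = (zero_sooner & (catch["choice"] == "later")) | (
        ~zero_sooner & (catch["choice"] == "sooner")
    )
    n_catch = len(catch)
    n_incorrect = int(n_catch - correct.sum())
    return QcReport(
        participant_id=pids[0],
        n_catch=n_catch,
        n_catch_incorrect=n_incorrect,
        excluded=n_incorrect > n_catch / 2,
    )


def qc_cohort(trials: pd.DataFrame) -> pd.DataFrame:
    """Score catch trials per participant; one row per participant."""
    reports = [
        score_catch_trials(sub) for _, sub in trials.groupby("participant_id", sort=True)
    ]
    return pd.DataFrame([r.__dict__ for r in reports])


def apply_exclusions(trials: pd.DataFrame, qc: pd.DataFrame) -> pd.DataFrame:
    """Drop trials of excluded participants (the QC table retains everyone)."""
    keep = qc.loc[~qc["excluded"], "participant_id"]
    return trials[trials["participant_id"].isin(keep)].copy()
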