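"""Trial tables: the tidy on-disk and in-memory representation of choice data.

One row per choice with columns ``participant_id, group, condition,
amount_ll, delay_days, choice_ll`` (comma-separated text, header mandatory,
UTF-8).  ``choice_ll`` is 1 when the larger-later option was taken.  An
optional ``tag`` column carries episodic event labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["ChoiceDataset", "REQUIRED_COLUMNS", "load_trials", "save_trials"]

REQUIRED_COLUMNS = (
    "participant_id", "group", "condition", "amount_ll", "delay_days", "choice_ll",
)

GROUPS = ("gambler", "control")
CONDITIONS = ("control", "episodic")


@dataclass
class ChoiceDataset:
    """Validated collection of participants x trials x observed choices.

    Parameters
    ----------
    trials : pandas.DataFrame
        Must contain :data:`REQUIRED_COLUMNS`.  Invalid rows (missing
        values, nonpositive amounts, negative delays, choices outside
        {0, 1}) are dropped with a recorded count, never imputed.
    allow_small_amounts : bool
        Permit LL amounts at or below the 20-euro SS amount (the study's
        offers always exceed it).
    """

    trials: pd.DataFrame
    allow_small_amounts: bool = False
    n_dropped: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        df = self.trials
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table lacks required columns: {missing}")
        df = df.copy()
        df["amount_ll"] = pd.to_numeric(df["amount_ll"], errors="coerce")
        df["delay_days"] = pd.to_numeric(df["delay_days"], errors="coerce")
        df["choice_ll"] = pd.to_numeric(df["choice_ll"], errors="coerce")
        ok = (
            df[list(REQUIRED_COLUMNS)].notna().all(axis=1)
            & (df["amount_ll"] > 0)
            & (df["delay_days"] >= 0)
            & df["choice_ll"].isin([0, 1])
        )
        if not self.allow_small_amounts:
            ok &= df["amount_ll"] > 20.0
        self.n_dropped = int((~ok).sum())
        df = df.loc[ok].reset_index(drop=True)
        df["choice_ll"] = df["choice_ll"].astype(int)
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
        if len(df) == 0:
            raise ValueError("trial table contains no valid trials")
        self.trials = df

    @property
    def participants(self) -> list:
        """Participant ids in order of first appearance."""
        return list(dict.fromkeys(self.trials["participant_id"]))

    @property
    def conditions(self) -> list:
        return sorted(self.trials["condition"].unique())

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def group_of(self, participant_id) -> str:
        g = self.trials.loc[self.trials["participant_id"] == participant_id, "group"]
        if g.empty:
            raise KeyError(f"unknown participant {participant_id!r}")
        return str(g.iloc[0])

    def require_complete_conditions(self) -> None:
        """Raise if any participant lacks trials in a condition present overall."""
        conds = set(self.conditions)
        counts = self.trials.groupby("participant_id")["condition"].agg(set)
        incomplete = [pid for pid, seen in counts.items() if set(seen) != conds]
        if incomplete:
            raise ValueError(
                f"participants missing a condition: {incomplete[:5]}"
                + ("..." if len(incomplete) > 5 else "")
            )

    def subset(self, participant_ids: Iterable) -> "ChoiceDataset":
        ids = set(participant_ids)
        sub = self.trials[self.trials["participant_id"].isin(ids)].reset_index(drop=True)
        return ChoiceDataset(sub, allow_small_amounts=True)


def load_trials(path, allow_small_amounts: bool = False) -> ChoiceDataset:
    """Read a comma-separated trial table from ``path``."""
    df = pd.read_csv(path, encoding="utf-8")
    return ChoiceDataset(df, allow_small_amounts=allow_small_amounts)


def save_trials(dataset_or_frame, path) -> None:
    """Write a trial table as comma-separated UTF-8 text."""
    df = getattr(dataset_or_frame, "trials", dataset_or_frame)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
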