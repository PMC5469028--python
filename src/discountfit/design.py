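"""Construction of the two-condition episodic-discounting trial set.

A session mixes two trial types, randomized trial-wise:

* **episodic** trials whose delays are the participant's own future events
  (each carrying a short verbal tag such as "vacation Paris"), and
* **control** trials with delays sampled between one day and the longest
  event delay.

Larger-later amounts come in two halves per condition: a *linear* half on
an evenly spaced grid from 20.5 to 99.5 euros, and a *tailored* half drawn
around the participant's indifference point — the amount at which, given
the pretest discount rate ``k``, the delayed offer is subjectively worth
exactly the fixed 20-euro immediate option.  Tailoring concentrates offers
where choices are maximally informative about ``k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .data import ChoiceDataset
from .hierarchical import fit_individual_mle
from .models import indifference_amount

__all__ = [
    "EpisodicEvent",
    "DesignConfig",
    "TrialSet",
    "pretest_estimate",
    "simulate_pretest",
    "draw_tailored_amounts",
    "build_trials",
    "validate_trialset",
    "load_events",
]


@dataclass(frozen=True)
class EpisodicEvent:
    """A participant-specific future event used as an episodic tag."""

    label: str
    delay_days: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("event label must be nonempty")
        if self.delay_days < 1:
            raise ValueError("event delay must be at least one day")


@dataclass(frozen=True)
class DesignConfig:
    """Trial-count and amount-construction constants of the task.

    Defaults are the study constants: a fixed 20-euro immediate option,
    linear amounts spanning 20.5-99.5 euros, and tailored amounts jittered
    with SD 4 euros around the indifference point.
    """

    n_trials: int = 120
    ss_amount: float = 20.0
    linear_min: float = 20.5
    linear_max: float = 99.5
    tailored_sd: float = 4.0
    seed: int = 0
    #: "interleaved": control delays fall between consecutive sorted event
    #: delays (so the two conditions alternate in time distance), remainder
    #: uniform over [1, max event delay].  "uniform": all control delays
    #: uniform over that range.
    control_delay_mode: str = "interleaved"

    def __post_init__(self) -> None:
        if self.n_trials < 4 or self.n_trials % 4:
            raise ValueError("n_trials must be a positive multiple of 4 "
                             "(two conditions x linear/tailored halves)")
        if not (0 < self.ss_amount < self.linear_min < self.linear_max):
            raise ValueError("require 0 < ss_amount < linear_min < linear_max")
        if self.tailored_sd <= 0:
            raise ValueError("tailored_sd must be positive")
        if self.control_delay_mode not in ("interleaved", "uniform"):
            raise ValueError(f"unknown control_delay_mode {self.control_delay_mode!r}")


@dataclass
class TrialSet:
    """Ordered offers plus the provenance needed to regenerate them."""

    trials: pd.DataFrame  # amount_ll, delay_days, condition, tag, amount_half
    pretest_k: float
    config: DesignConfig
    events: List[EpisodicEvent]

    def save(self, csv_path, sidecar_path=None) -> None:
        Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(csv_path, index=False, encoding="utf-8")
        if sidecar_path is not None:
            meta = {
                "pretest_k": self.pretest_k,
                "config": asdict(self.config),
                "events": [asdict(e) for e in self.events],
            }
            Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def load_events(path) -> List[EpisodicEvent]:
    """Read a JSON array of {label, delay_days} event records."""
    raw = json.loads(Path(path).read_text())
    return [EpisodicEvent(label=e["label"], delay_days=float(e["delay_days"])) for e in raw]


def pretest_estimate(
    pretest_choices: ChoiceDataset,
    log_k_bounds=(np.log(1e-5), np.log(1.0)),
) -> float:
    """Single hyperbolic discount rate from one participant's pretest choices.

    A plain per-participant maximum-likelihood fit (no pooling).  Degenerate
    all-LL or all-SS response patterns carry no information about ``k``
    beyond "extremely patient/impulsive", so the estimate is clamped to the
    configured bounds with a warning.
    """
    df = pretest_choices.trials
    if df["participant_id"].nunique() != 1:
        raise ValueError("pretest_estimate expects exactly one participant")
    choices = df["choice_ll"].to_numpy()
    if choices.min() == choices.max():
        import warnings

        lo, hi = np.exp(log_k_bounds[0]), np.exp(log_k_bounds[1])
        k = lo if choices[0] == 1 else hi  # always-LL = patient = small k
        warnings.warn(
            f"degenerate all-{'LL' if choices[0] else 'SS'} pretest pattern; "
            f"k clamped to {k:g}", stacklevel=2,
        )
        return float(k)
    est = fit_individual_mle(pretest_choices, model="hyperbolic",
                             log_k_bounds=log_k_bounds)
    return float(np.exp(est["log_k"].iloc[0]))


def simulate_pretest(
    k_true: float,
    beta_true: float = 2.0,
    delays: Sequence[float] = (5, 15, 30, 60, 120, 200),
    steps_per_delay: int = 10,
    ss_amount: float = 20.0,
    seed: int = 0,
) -> ChoiceDataset:
    """Adaptive pretest session: a per-delay bisection staircase on LL amount.

    For each tested delay, the offered amount starts at the midpoint of
    [ss_amount, 100] and bisects toward the simulated participant's
    indifference point: an LL choice lowers the next offer, an SS choice
    raises it.  Choices are drawn from the hyperbolic + softmax model with
    the given true parameters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in delays:
        lo, hi = ss_amount + 0.5, 100.0
        for _ in range(steps_per_delay):
            amount = 0.5 * (lo + hi)
            sv = amount / (1.0 + k_true * d)
            p = 1.0 / (1.0 + np.exp(-(sv - ss_amount) / beta_true))
            choice = int(rng.random() < p)
            rows.append({"participant_id": "pretest", "group": "control",
                         "condition": "control", "amount_ll": amount,
                         "delay_days": d, "choice_ll": choice})
            if choice:
                hi = amount  # LL taken: offer less next time
            else:
                lo = amount
    return ChoiceDataset(pd.DataFrame(rows), allow_small_amounts=True)


def draw_tailored_amounts(
    k: float,
    delays,
    rng: np.random.Generator,
    ss_amount: float = 20.0,
    sd: float = 4.0,
    truncate_at: Optional[float] = 20.5,
) -> np.ndarray:
    """Draw LL amounts Normal(indifference point, sd) for the given delays.

    With ``truncate_at`` set, draws below that floor are resampled so every
    offer remains a genuine larger-later amount; ``truncate_at=None``
    disables truncation (raw normal draws).
    """
    delays = np.asarray(delays, dtype=float)
    mean = indifference_amount(k, delays, ss_amount)
    amounts = rng.normal(mean, sd)
    if truncate_at is not None:
        for _ in range(1000):
            low = amounts < truncate_at
            if not low.any():
                break
            amounts[low] = rng.normal(mean[low], sd)
        else:
            amounts = np.maximum(amounts, truncate_at)
    return amounts


def _control_delays(events_sorted: np.ndarray, n: int, mode: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Integer control-condition delays in [1, max event delay]."""
    dmax = int(np.ceil(events_sorted[-1]))
    if mode == "uniform" or len(events_sorted) < 2:
        return rng.integers(1, dmax + 1, size=n).astype(float)
    # interleave: one delay between each pair of consecutive event delays
    out = []
    bounds = np.ceil(events_sorted).astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if len(out) >= n:
            break
        lo_, hi_ = min(lo, hi), max(lo, hi)
        out.append(int(rng.integers(max(1, lo_), max(1, lo_, hi_) + 1)))
    while len(out) < n:
        out.append(int(rng.integers(1, dmax + 1)))
    return np.array(out[:n], dtype=float)


def build_trials(k: float, events: Sequence[EpisodicEvent],
                 config: DesignConfig = DesignConfig()) -> TrialSet:
    """Assemble the full two-condition trial set for one participant.

    Per condition, half the amounts form the evenly spaced linear grid over
    [linear_min, linear_max] and half are tailored around the indifference
    point of each trial's delay.  Episodic delays cycle over the event
    list; control delays are sampled per ``config.control_delay_mode``.
    The final trial order is shuffled by the seeded generator.
    """
    if k <= 0:
        raise ValueError("pretest k must be positive")
    events = list(events)
    if not events:
        raise ValueError("need at least one episodic event")
    rng = np.random.default_rng(config.seed)
    n_cond = config.n_trials // 2
    n_linear = n_cond // 2

    event_delays = np.array([e.delay_days for e in events], dtype=float)
    order = np.argsort(event_delays)
    sorted_delays = event_delays[order]

    frames = []
    for condition in ("control", "episodic"):
        if condition == "episodic":
            idx = np.arange(n_cond) % len(events)
            delays = event_delays[idx]
            tags = [events[i].label for i in idx]
        else:
            delays = _control_delays(sorted_delays, n_cond,
                                     config.control_delay_mode, rng)
            tags = [None] * n_cond
        amounts = np.empty(n_cond)
        amounts[:n_linear] = np.linspace(config.linear_min, config.linear_max, n_linear)
        amounts[n_linear:] = draw_tailored_amounts(
            k, delays[n_linear:], rng, config.ss_amount,
            config.tailored_sd, truncate_at=config.linear_min,
        )
        frames.append(pd.DataFrame({
            "amount_ll": amounts, "delay_days": delays, "condition": condition,
            "tag": tags,
            "amount_half": ["linear"] * n_linear + ["tailored"] * (n_cond - n_linear),
        }))
    df = pd.concat(frames, ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return TrialSet(trials=df, pretest_k=float(k), config=config, events=events)


def validate_trialset(trialset: TrialSet) -> pd.DataFrame:
    """Machine-readable invariant report for a trial set (never raises)."""
    df = trialset.trials
    cfg = trialset.config
    ep = df[df["condition"] == "episodic"]
    ct = df[df["condition"] == "control"]
    lin = df[df["amount_half"] == "linear"]
    tail = df[df["amount_half"] == "tailored"]
    max_delay = max(e.delay_days for e in trialset.events)
    checks = [
        ("both_conditions_present", len(ep) > 0 and len(ct) > 0),
        ("episodic_trials_tagged", bool(ep["tag"].notna().all()) if len(ep) else False),
        ("control_trials_untagged", bool(ct["tag"].isna().all()) if len(ct) else False),
        ("condition_balance", len(ep) == len(ct)),
        ("linear_min_exact", bool(len(lin)) and float(lin["amount_ll"].min()) == cfg.linear_min),
        ("linear_max_exact", bool(len(lin)) and float(lin["amount_ll"].max()) == cfg.linear_max),
        ("tailored_above_ss", bool((tail["amount_ll"] > cfg.ss_amount).all()) if len(tail) else True),
        ("control_delays_in_range",
         bool(((ct["delay_days"] >= 1) & (ct["delay_days"] <= max_delay)).all()) if len(ct) else False),
        ("episodic_delays_from_events",
         bool(ep["delay_days"].isin([e.delay_days for e in trialset.events]).all()) if len(ep) else False),
        ("amounts_positive", bool((df["amount_ll"] > 0).all())),
    ]
    return pd.DataFrame(checks, columns=["check", "passed"])
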