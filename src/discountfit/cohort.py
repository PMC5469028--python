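"""Synthetic two-group, two-condition cohorts with known ground truth.

Emulates the study design — pathological gamblers vs. healthy controls,
each choosing between 20 euros now and tailored larger-later offers under
an episodic (event-tagged) and a control condition — by forward-simulating
the hierarchical generative model: individual log discount rates drawn
from group-level normals (gamblers shifted toward steeper discounting), a
small negative condition effect on log(k) in the episodic condition (the
"tag-effect"), softmax decision noise, and Bernoulli choices.

Every simulation returns (and, when written to disk, stores) its ground
truth, so each synthetic run doubles as a parameter-recovery experiment.
The default parameter magnitudes are package choices calibrated to
plausible day-scale discounting; the source study reports test statistics
only, not generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .data import ChoiceDataset, save_trials
from .design import DesignConfig, EpisodicEvent, build_trials
from .models import choice_probability, DiscountParams, ChoicePolicy

__all__ = ["CohortSpec", "CohortTruth", "simulate_cohort", "fixture_suite"]


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic cohort.

    ``mean_logk`` maps group name to the control-condition mean of log(k);
    the episodic condition adds ``delta_logk`` (negative = shallower
    discounting under episodic tags) plus individual jitter with SD
    ``sd_delta_logk``.
    """

    n_per_group: int = 24
    trials_per_participant: int = 120
    mean_logk: Dict[str, float] = field(
        default_factory=lambda: {"control": -4.5, "gambler": -3.8}
    )
    sd_logk: float = 0.8
    delta_logk: float = -0.2
    sd_delta_logk: float = 0.15
    mean_logbeta: float = 0.7
    sd_logbeta: float = 0.4
    #: correlation loading of the severity covariate on z-scored log(k)
    severity_loading: float = 0.3
    model: str = "hyperbolic"
    events_per_participant: Tuple[int, int] = (5, 7)
    max_event_delay: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 participants per group")
        if self.sd_logk <= 0 or self.sd_logbeta <= 0 or self.sd_delta_logk < 0:
            raise ValueError("spread parameters must be positive")
        if self.trials_per_participant % 4:
            raise ValueError("trials_per_participant must be a multiple of 4")
        if self.model not in ("hyperbolic", "exponential", "constant_sensitivity"):
            raise ValueError(f"unsupported generating model {self.model!r}")
        if not set(self.mean_logk) >= {"control", "gambler"}:
            raise ValueError("mean_logk must cover groups 'control' and 'gambler'")


@dataclass
class CohortTruth:
    """Ground-truth parameters of one simulated cohort."""

    participants: pd.DataFrame  # participant_id, group, logk per condition, logbeta, severity
    spec: CohortSpec
    seed: int

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "spec": asdict(self.spec),
            "participants": self.participants.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "CohortTruth":
        raw = json.loads(Path(path).read_text())
        spec_raw = raw["spec"]
        spec_raw["events_per_participant"] = tuple(spec_raw["events_per_participant"])
        return cls(
            participants=pd.DataFrame(raw["participants"]),
            spec=CohortSpec(**spec_raw), seed=raw["seed"],
        )


_EVENT_POOL = [
    "birthday party", "vacation", "concert", "wedding", "family visit",
    "exam", "dentist", "moving day", "job interview", "festival",
]


def _participant_events(rng: np.random.Generator, spec: CohortSpec) -> List[EpisodicEvent]:
    lo, hi = spec.events_per_participant
    n = int(rng.integers(lo, hi + 1))
    delays = np.sort(rng.integers(3, int(spec.max_event_delay) + 1, size=n))
    labels = rng.choice(_EVENT_POOL, size=n, replace=False)
    return [EpisodicEvent(label=f"{lab} (+{d}d)", delay_days=float(d))
            for lab, d in zip(labels, delays)]


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> Tuple[ChoiceDataset, CohortTruth]:
    """Forward-simulate a full cohort from the hierarchical generative model.

    Each participant's trial set is built by the task designer using their
    true control-condition discount rate as the "pretest" rate, mirroring
    how the real task tailors offers to the pretest session.  Fully
    determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    truth_rows = []
    trial_frames = []
    for group in ("gambler", "control"):
        for i in range(spec.n_per_group):
            pid = f"{group[0]}{i + 1:02d}"
            logk_control = rng.normal(spec.mean_logk[group], spec.sd_logk)
            logk_episodic = logk_control + spec.delta_logk + rng.normal(0.0, spec.sd_delta_logk)
            logbeta = rng.normal(spec.mean_logbeta, spec.sd_logbeta)
            events = _participant_events(rng, spec)
            design = DesignConfig(
                n_trials=spec.trials_per_participant,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trialset = build_trials(np.exp(logk_control), events, design)
            df = trialset.trials.copy()
            logk_by_cond = {"control": logk_control, "episodic": logk_episodic}
            choices = np.empty(len(df), dtype=int)
            for cond, sub in df.groupby("condition", sort=False):
                params = DiscountParams(model=spec.model, k=float(np.exp(logk_by_cond[cond])),
                                        s=1.0 if spec.model == "constant_sensitivity" else None)
                p = choice_probability(
                    params, ChoicePolicy(beta=float(np.exp(logbeta))),
                    sub["amount_ll"].to_numpy(), sub["delay_days"].to_numpy(),
                    design.ss_amount,
                )
                choices[sub.index.to_numpy()] = (rng.random(len(sub)) < p).astype(int)
            df["choice_ll"] = choices
            df["participant_id"] = pid
            df["group"] = group
            trial_frames.append(df)
            severity_noise = rng.standard_normal()
            truth_rows.append({
                "participant_id": pid, "group": group,
                "logk_control": logk_control, "logk_episodic": logk_episodic,
                "logbeta": logbeta, "_severity_noise": severity_noise,
            })

    truth = pd.DataFrame(truth_rows)
    # placeholder severity covariate: loading on z-scored control log(k)
    z = (truth["logk_control"] - truth["logk_control"].mean()) / truth["logk_control"].std()
    lam = spec.severity_loading
    truth["severity"] = lam * z + np.sqrt(max(0.0, 1 - lam**2)) * truth.pop("_severity_noise")

    trials = pd.concat(trial_frames, ignore_index=True)
    cols = ["participant_id", "group", "condition", "amount_ll", "delay_days",
            "choice_ll", "tag", "amount_half"]
    dataset = ChoiceDataset(trials[cols], allow_small_amounts=True)
    return dataset, CohortTruth(participants=truth, spec=spec, seed=spec.seed)


def write_cohort(dataset: ChoiceDataset, truth: CohortTruth, outdir) -> None:
    """Write trials.csv + truth.json; simulations are never stored truthless."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_trials(dataset, outdir / "trials.csv")
    truth.save(outdir / "truth.json")


def fixture_suite(seed: int = 0) -> Dict[str, ChoiceDataset]:
    """Tiny deterministic datasets for module tests.

    Keys: ``one_participant`` (60 trials), ``two_participant`` (2 x 40
    trials, both conditions), ``all_ll`` / ``all_ss`` (degenerate response
    patterns).  Same seed, same bytes.
    """
    rng = np.random.default_rng(seed)

    def _mini(pids, n_trials, force_choice=None):
        rows = []
        for pid, group in pids:
            logk = rng.normal(-4.0, 0.5)
            for t in range(n_trials):
                cond = "control" if t % 2 == 0 else "episodic"
                amount = float(rng.uniform(20.5, 99.5))
                delay = float(rng.integers(1, 180))
                if force_choice is None:
                    sv = amount / (1 + np.exp(logk) * delay)
                    p = 1 / (1 + np.exp(-(sv - 20.0) / 2.0))
                    choice = int(rng.random() < p)
                else:
                    choice = force_choice
                rows.append({"participant_id": pid, "group": group,
                             "condition": cond, "amount_ll": amount,
                             "delay_days": delay, "choice_ll": choice})
        return ChoiceDataset(pd.DataFrame(rows), allow_small_amounts=True)

    return {
        "one_participant": _mini([("p01", "control")], 60),
        "two_participant": _mini([("p01", "control"), ("g01", "gambler")], 40),
        "all_ll": _mini([("p01", "control")], 30, force_choice=1),
        "all_ss": _mini([("p01", "control")], 30, force_choice=0),
    }
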