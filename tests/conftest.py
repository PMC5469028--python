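import warnings

import numpy as np
import pandas as pd
import pytest

from discountfit import (
    ChoiceDataset, CohortSpec, HierarchyConfig, fit_hierarchical,
    fixture_suite, simulate_cohort,
)

#: reduced sampler settings for test-scale fits
FAST_FIT = dict(chains=2, draws=300, warmup=400, thin=2, ess_min=50.0, rhat_max=1.1)


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """6 participants per group, 60 trials each; known ground truth."""
    spec = CohortSpec(n_per_group=6, trials_per_participant=60, seed=21)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One reduced-size hierarchical fit shared across tests."""
    dataset, truth = small_cohort
    config = HierarchyConfig(model="hyperbolic", seed=7, **FAST_FIT)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_hierarchical(dataset, config)
    return dataset, truth, draws


@pytest.fixture
def tiny_trials():
    """Five hand-constructed trials for one participant, both conditions."""
    return ChoiceDataset(pd.DataFrame({
        "participant_id": ["p1"] * 5,
        "group": ["control"] * 5,
        "condition": ["control", "control", "episodic", "episodic", "control"],
        "amount_ll": [40.0, 55.0, 62.5, 30.0, 99.5],
        "delay_days": [10, 45, 100, 5, 180],
        "choice_ll": [1, 0, 1, 1, 0],
    }))
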