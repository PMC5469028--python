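"""Simulate a small cohort and recover its parameters hierarchically.

Generates choices for 6 gamblers and 6 controls (60 trials each) from the
hyperbolic + softmax model with known individual log(k), fits the
hierarchical model by MCMC, and compares estimated to true values.
Runs in well under a minute on one CPU.
"""

import numpy as np

from discountfit import (
    CohortSpec, HierarchyConfig, fit_hierarchical, point_estimates,
    simulate_cohort,
)

spec = CohortSpec(n_per_group=6, trials_per_participant=60, seed=21)
dataset, truth = simulate_cohort(spec)
print(f"simulated {dataset.n_trials} trials, "
      f"{len(truth.participants)} participants")

config = HierarchyConfig(chains=2, draws=500, warmup=500, seed=7,
                         ess_min=100, rhat_max=1.05)
draws = fit_hierarchical(dataset, config)
print(f"sampling done: {draws.n_samples} kept draws, converged={draws.converged}")

est = point_estimates(draws)
tr = truth.participants.melt(
    id_vars=["participant_id", "group"],
    value_vars=["logk_control", "logk_episodic"],
    var_name="condition", value_name="true_logk",
)
tr["condition"] = tr["condition"].str.replace("logk_", "")
m = est.merge(tr, on=["participant_id", "group", "condition"])
r = np.corrcoef(m["log_k"], m["true_logk"])[0, 1]
print(m[["participant_id", "condition", "true_logk", "log_k"]]
      .head(6).to_string(index=False))
print(f"\ncorrelation(true, estimated log k) = {r:.3f}")
print("Values near 1 mean the hierarchical fit recovers individual "
      "discount rates; shrinkage pulls poorly-informed participants "
      "toward their group mean.")
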