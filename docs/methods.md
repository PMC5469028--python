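# Methods

## The choice model

A trial offers a fixed smaller-sooner reward (20 € immediately) against a
larger-later reward of amount *A* euros at delay *D* days. Four candidate
models turn the offer into a choice probability:

| model | value / rule | free parameters |
|---|---|---|
| hyperbolic | SV = A / (1 + k·D) | k (rate/day), β |
| exponential (discounted utility) | SV = A·exp(−k·D) | k, β |
| constant sensitivity | SV = A·exp(−(k·D)^s) | k, s, β |
| ITCH | logit P(LL) = w₀ + w₁·ΔA + w₂·ΔA/Ā + w₃·ΔD + w₄·ΔD/D̄ | five weights |

The three value-based models share the softmax (two-option logistic)
policy P(LL) = 1/(1 + exp(−(SV − 20)/β)); β is in euros, larger β = noisier
choices. The exponential, constant-sensitivity and ITCH parameterizations
follow their standard formulations in the discounting literature; they are
fixed conventions of this package. The ITCH relative-delay denominator is
max(mean delay, 1) day so an immediate reference option is well-defined.

Numerical conventions: the softmax is evaluated as a logistic of the value
difference (the ratio-of-exponentials form overflows for small β); choice
probabilities are clamped to [1e−12, 1 − 1e−12] before logs so pointwise
log-likelihoods stay finite under extreme parameter draws; delays are in
days everywhere.

## Hierarchical estimation

Both k and β are estimated on the log scale (their sampling distributions
are strongly right-skewed). For participant *i* in condition *c* of group
*g*:

    log k[i,c] ~ Normal(mu_k[g,c], sigma_k[g,c])
    log β[i,c] ~ Normal(mu_b[g,c], sigma_b[g,c])
    choice     ~ Bernoulli(P(LL))

with hyperpriors mu_k ~ Normal(−4.5, 2), sigma_k ~ HalfNormal(2),
mu_b ~ Normal(0.7, 1.5), sigma_b ~ HalfNormal(1). The mu_k prior centers on
k ≈ 0.011/day — mid-range for day-scale human discounting — and its scale
spans k from ~1e−4 to ~1 without dominating 100+ trials per participant.
Each group × condition cell has its own hyperparameters inside one joint
model (a `by_condition` pooling option merges the groups); priors,
chain/draw counts and gates are all configurable on `HierarchyConfig`.

The sampler is Metropolis-within-Gibbs, exploiting that participants are
conditionally independent given the hyperparameters:

1. single-site adaptive random-walk updates of each individual parameter,
   vectorized across all participant × condition blocks;
2. exact conjugate normal draws for the group means;
3. slice sampling of each group SD's univariate conditional;
4. a non-centered interweaving move that rescales a whole cell's individual
   parameters together with its SD. Without it the chain stalls in the
   "funnel" whenever a parameter (typically log β) is weakly identified per
   participant and sigma mixes at ESS ≈ 20; with it the same fits reach
   R-hat ≤ 1.01.

Proposal scales adapt toward 40% acceptance during warmup only, so kept
draws form a valid Markov chain. Defaults: 4 chains × 1000 kept draws after
1000 warmup sweeps, thinned by 3; seeds derive from one integer via numpy's
SeedSequence, making fits bit-reproducible. Convergence is gated on split
R-hat ≤ 1.01 and bulk ESS ≥ 400 for every sampled parameter (arviz); a
failing fit is returned flagged with warnings, never silently. Invalid
trial rows are dropped with a recorded count, never imputed.

Every fit stores the trials × samples pointwise log-likelihood matrix
alongside the draws; `recompute_loglik` can regenerate it from the stored
parameter draws as a cross-check. Draws persist as an `.npz` bundle with a
JSON metadata sidecar (seed, config hash); an in-memory
`arviz.InferenceData` view is available via `to_inferencedata()`.

## WAIC

From the pointwise matrix, lppd = Σᵢ log(meanₛ exp(llᵢₛ)) (log-sum-exp
guarded) and p_waic = Σᵢ varₛ(llᵢₛ) with the n−1 sample-variance
denominator (the variance form of the penalty); WAIC = −2(lppd − p_waic) on
the deviance scale, so lower is better. A single-sample matrix has exactly
zero penalty. WAIC is computed over whatever trial set it is given —
pooling all participants gives one total per model.

## Trial design

Given a pretest discount rate k (per-participant maximum-likelihood
hyperbolic fit; the simulated pretest is a per-delay bisection staircase on
the LL amount), the designer builds `n_trials` offers, half per condition:

- **linear half**: amounts evenly spaced over [20.5, 99.5] €;
- **tailored half**: amounts ~ Normal(20·(1 + k·D), 4 €) around each
  trial's indifference point. Draws below 20.5 € are resampled so every
  offer remains a genuine larger-later reward (the truncation rate is tiny
  except for near-zero k; `draw_tailored_amounts(..., truncate_at=None)`
  gives the raw distribution);
- **episodic delays** cycle over the participant's event list (5–7 events,
  days to ~200 days out, each with a verbal tag);
- **control delays** are whole days in [1, max event delay]. The default
  `interleaved` mode places one control delay uniformly between each pair
  of consecutive sorted event delays (so the two conditions alternate in
  time distance — an interpretation; `uniform` mode is the plain
  alternative), remainder uniform over the full range.

Trial order is shuffled by the seeded generator; builds are
bit-reproducible.

## Synthetic cohorts

`simulate_cohort` forward-simulates the full generative model: individual
log k drawn from group normals, the episodic value shifted by the condition
effect δ plus Normal(0, 0.15) individual jitter (giving realistic
within-person correlation between conditions), log β from its own normal,
per-participant trial sets built by the designer using the true
control-condition k as the "pretest" rate, and Bernoulli choices from the
generating model. Defaults — 24 per group, 120 trials each, control-group
mean log k = −4.5, gambler offset +0.7, δ = −0.2, sd(log k) = 0.8,
mean log β = 0.7, sd 0.4 — are package choices at plausible magnitudes; the
motivating study reports test statistics, not generating values, so these
are explicitly not empirical estimates. A placeholder severity covariate
loads 0.3 on z-scored baseline log k. Ground truth is always returned and
always written beside simulated data.

What the simulations do *not* emulate: session structure and order effects,
reaction times, attention lapses or choice perseveration, event imageability
differences, and any imaging-related quantity. Passing recovery tests
therefore show the estimator works when the model is true — they do not
validate the model against real behaviour.

## Group statistics

- tag-effect = log(k)_control − log(k)_episodic per participant (positive =
  less impulsive under tags).
- Mixed ANOVA (group between × condition within) uses the classical
  two-way partitioning with participant as the within-subject block and
  weighted marginal means; degenerate zero-error inputs return F = 0 rather
  than 0/0. Cross-checked against pingouin on balanced designs in the tests.
- Severity = mean of the two instruments' within-cohort z-scores; its
  association with baseline log k is a one-sided (positive) Pearson test
  within gamblers.
- The tag-effect regression is OLS on group, age, education, income, FTND,
  AUDIT, BDI, imagery, baseline log k, plus severity and the severity × BDI
  interaction; predictors are not standardized; rank-deficient designs
  raise an error naming the collinear columns.
- The improvement-proportion comparison is a 2×2 chi-square with Yates
  continuity correction on by default (configurable).
- Demographic comparisons use Welch's unequal-variance t-test.
- No multiple-testing correction is applied across the battery.

## Validation scale and known limitations

The heavy validation runs use reduced problem sizes chosen as package
defaults for desk-scale testing: parameter recovery at 2 groups × 12
participants × 120 trials with 2 chains × 500 kept draws (thin 2);
model recovery over 20 datasets per generating model at 12 participants ×
120 trials with 2 chains × 200 draws; statistical calibration at 10,000
null replicates. Production fits should use the 4 × 1000 defaults.

Limitations: the random-walk sampler, while validated by recovery and
calibration tests, mixes more slowly than gradient-based samplers for the
ITCH model's five correlated weights; WAIC totals depend on the trial set
supplied and are not comparable across datasets; the pretest staircase is
one reasonable instantiation of an adaptive pretest, not a reconstruction
of any specific published procedure; and model recovery is only tested
between the hyperbolic and exponential forms, where the discrimination
problem is hardest among the value-based models.
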