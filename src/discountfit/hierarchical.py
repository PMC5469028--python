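"""Hierarchical Bayesian estimation of discounting and decision-noise parameters.

The probability model
---------------------

For every participant *i* and condition *c* the selected choice model has a
small parameter vector ``theta[i, c]`` (e.g. ``log k`` and ``log beta`` for
the hyperbolic model; discount rates and softmax temperatures are sampled on
the log scale and exponentiated inside the likelihood).  Individual
parameters are drawn from group-level normal distributions

    theta[i, c, p] ~ Normal(mu[g(i), c, p], sigma[g(i), c, p])

with weakly-informative hyperpriors ``mu ~ Normal(m0, s0)`` and
``sigma ~ HalfNormal(tau)``.  Observed choices are Bernoulli with the
model's choice probability.  Partial pooling toward the group mean shrinks
noisy individual estimates, which is what makes per-participant rates
estimable from ~100 trials.

The sampler
-----------

Metropolis-within-Gibbs: individual parameters get single-site adaptive
Gaussian random-walk updates (participants are conditionally independent
given the hyperparameters, so all blocks update in one vectorized sweep);
group means are updated by their exact conjugate normal conditional; group
SDs by slice sampling of their (cheap) conditional.  An additional
non-centered interweaving move rescales a whole group's individual
parameters together with its SD, which breaks the funnel geometry that
otherwise stalls hierarchical scale parameters when individuals are weakly
identified.  Proposal scales adapt toward a target acceptance rate during
warmup only, so the kept draws form a valid Markov chain.  Multiple chains
run from jittered starts; convergence is gated on split R-hat and bulk
effective sample size (computed with arviz).

Alongside the draws the fit accumulates the trials-by-samples pointwise
log-likelihood matrix that WAIC model comparison consumes.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .data import ChoiceDataset
from .models import PROB_FLOOR, VALUE_MODELS, MODELS, _itch_prob_arrays

__all__ = [
    "HierarchyConfig",
    "PosteriorDraws",
    "fit_hierarchical",
    "point_estimates",
    "fit_individual_mle",
    "recompute_loglik",
]

_PARAM_NAMES = {
    "hyperbolic": ["log_k", "log_beta"],
    "exponential": ["log_k", "log_beta"],
    "constant_sensitivity": ["log_k", "log_beta", "log_s"],
    "itch": ["w_intercept", "w_amount_abs", "w_amount_rel", "w_delay_abs", "w_delay_rel"],
}

_ADAPT_TARGET = 0.40  # single-site random-walk acceptance target


@dataclass
class HierarchyConfig:
    """Priors, sampler settings and pooling scheme for one hierarchical fit.

    Prior defaults span empirically plausible day-scale discounting
    (``exp(-4.5) ~ 0.011`` per day) and euro-scale softmax temperatures
    without dominating 100+ trials per participant.
    """

    model: str = "hyperbolic"
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    #: inner MCMC sweeps per kept draw; >1 decorrelates kept samples
    thin: int = 3
    #: "by_group_condition" gives each group x condition cell its own
    #: hyperparameters; "by_condition" pools the groups.
    pooling: str = "by_group_condition"
    prior_mu_logk: float = -4.5
    prior_sd_logk: float = 2.0
    prior_sigma_scale_logk: float = 2.0
    prior_mu_logbeta: float = 0.7
    prior_sd_logbeta: float = 1.5
    prior_sigma_scale_logbeta: float = 1.0
    prior_mu_logs: float = 0.0
    prior_sd_logs: float = 0.5
    prior_sigma_scale_logs: float = 0.5
    prior_mu_itch: float = 0.0
    prior_sd_itch: float = 2.0
    prior_sigma_scale_itch: float = 1.0
    rhat_max: float = 1.01
    ess_min: float = 400.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat")
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws must be >= 1 and warmup >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.pooling not in ("by_group_condition", "by_condition"):
            raise ValueError(f"unknown pooling scheme {self.pooling!r}")
        for f_ in ("prior_sd_logk", "prior_sigma_scale_logk", "prior_sd_logbeta",
                   "prior_sigma_scale_logbeta", "prior_sd_logs",
                   "prior_sigma_scale_logs", "prior_sd_itch", "prior_sigma_scale_itch"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")

    @property
    def param_names(self) -> List[str]:
        return list(_PARAM_NAMES[self.model])

    def prior_for(self, param: str) -> Tuple[float, float, float]:
        """(hypermean location, hypermean scale, half-normal scale of sigma)."""
        if param == "log_k":
            return self.prior_mu_logk, self.prior_sd_logk, self.prior_sigma_scale_logk
        if param == "log_beta":
            return self.prior_mu_logbeta, self.prior_sd_logbeta, self.prior_sigma_scale_logbeta
        if param == "log_s":
            return self.prior_mu_logs, self.prior_sd_logs, self.prior_sigma_scale_logs
        return self.prior_mu_itch, self.prior_sd_itch, self.prior_sigma_scale_itch

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PosteriorDraws:
    """MCMC output: individual and group-level draws plus the pointwise
    log-likelihood matrix and convergence diagnostics.

    ``theta`` has shape (chains, draws, n_blocks, n_params) where a block is
    one participant x condition cell; ``mu``/``sigma`` have shape
    (chains, draws, n_cells, n_params).
    """

    theta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    loglik: np.ndarray  # (chains, draws, n_trials)
    param_names: List[str]
    block_participant: List
    block_condition: List[str]
    block_group: List[str]
    cell_labels: List[str]
    diagnostics: pd.DataFrame
    converged: bool
    warnings: List[str]
    config: HierarchyConfig
    seed: int

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    @property
    def loglik_matrix(self) -> np.ndarray:
        """Trials-by-samples pointwise log-likelihood matrix."""
        c, d, n = self.loglik.shape
        return self.loglik.reshape(c * d, n).T

    def param_draws(self, param: str) -> np.ndarray:
        """Flattened (samples, n_blocks) draws of one individual parameter."""
        try:
            j = self.param_names.index(param)
        except ValueError:
            raise KeyError(
                f"parameter {param!r} is not sampled by the "
                f"{self.config.model} model (has: {self.param_names})"
            ) from None
        c, d, b, _ = self.theta.shape
        return self.theta[..., j].reshape(c * d, b)

    def to_inferencedata(self) -> az.InferenceData:
        """View the draws as an arviz InferenceData (in memory)."""
        posterior = {}
        for j, name in enumerate(self.param_names):
            posterior[name] = self.theta[..., j]
            posterior[f"mu_{name}"] = self.mu[..., j]
            posterior[f"sigma_{name}"] = self.sigma[..., j]
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"choice_ll": self.loglik},
            coords={"block": np.arange(self.theta.shape[2]),
                    "cell": np.arange(self.mu.shape[2])},
            dims={name: ["block"] for name in self.param_names}
            | {f"mu_{n}": ["cell"] for n in self.param_names}
            | {f"sigma_{n}": ["cell"] for n in self.param_names},
        )

    def save(self, outdir) -> None:
        """Persist draws (npz), summaries (csv) and run metadata (json)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            outdir / "draws.npz",
            theta=self.theta, mu=self.mu, sigma=self.sigma, loglik=self.loglik,
        )
        meta = {
            "param_names": self.param_names,
            "block_participant": [str(p) for p in self.block_participant],
            "block_condition": self.block_condition,
            "block_group": self.block_group,
            "cell_labels": self.cell_labels,
            "converged": self.converged,
            "warnings": self.warnings,
            "seed": int(self.seed),
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
        self.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)
        point_estimates(self).to_csv(outdir / "estimates.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        outdir = Path(outdir)
        arrs = np.load(outdir / "draws.npz")
        meta = json.loads((outdir / "meta.json").read_text())
        return cls(
            theta=arrs["theta"], mu=arrs["mu"], sigma=arrs["sigma"],
            loglik=arrs["loglik"], param_names=meta["param_names"],
            block_participant=meta["block_participant"],
            block_condition=meta["block_condition"],
            block_group=meta["block_group"], cell_labels=meta["cell_labels"],
            diagnostics=pd.read_csv(outdir / "diagnostics.csv"),
            converged=meta["converged"], warnings=meta["warnings"],
            config=HierarchyConfig(**meta["config"]), seed=meta["seed"],
        )


class _Problem:
    """Index structure and vectorized likelihood for one dataset + model."""

    def __init__(self, dataset: ChoiceDataset, config: HierarchyConfig,
                 ss_amount: float = 20.0):
        dataset.require_complete_conditions()
        df = dataset.trials
        self.model = config.model
        self.ss_amount = float(ss_amount)
        self.amount = df["amount_ll"].to_numpy(float)
        self.delay = df["delay_days"].to_numpy(float)
        self.choice = df["choice_ll"].to_numpy(int)

        blocks = (
            df[["participant_id", "condition", "group"]]
            .drop_duplicates(["participant_id", "condition"])
            .reset_index(drop=True)
        )
        self.block_participant = blocks["participant_id"].tolist()
        self.block_condition = blocks["condition"].tolist()
        self.block_group = blocks["group"].astype(str).tolist()
        key_to_block = {
            (p, c): i
            for i, (p, c) in enumerate(zip(self.block_participant, self.block_condition))
        }
        self.trial_block = df.apply(
            lambda r: key_to_block[(r["participant_id"], r["condition"])], axis=1
        ).to_numpy(int)
        self.n_blocks = len(blocks)

        if config.pooling == "by_group_condition":
            cells = sorted({(g, c) for g, c in zip(self.block_group, self.block_condition)})
            self.cell_labels = [f"{g}/{c}" for g, c in cells]
            cell_index = {gc: i for i, gc in enumerate(cells)}
            self.block_cell = np.array(
                [cell_index[(g, c)] for g, c in zip(self.block_group, self.block_condition)]
            )
        else:
            cells = sorted(set(self.block_condition))
            self.cell_labels = list(cells)
            cell_index = {c: i for i, c in enumerate(cells)}
            self.block_cell = np.array([cell_index[c] for c in self.block_condition])
        self.n_cells = len(self.cell_labels)
        self.n_params = len(config.param_names)

    def trial_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial Bernoulli log-likelihood for block parameters theta (B, P)."""
        tb = theta[self.trial_block]  # (n_trials, P)
        if self.model in VALUE_MODELS:
            # clip log-scale params so exp cannot over/underflow during
            # early exploration; the prior keeps the chain far from these
            k = np.exp(np.clip(tb[:, 0], -300.0, 300.0))
            beta = np.exp(np.clip(tb[:, 1], -300.0, 300.0))
            if self.model == "hyperbolic":
                sv = self.amount / (1.0 + k * self.delay)
            elif self.model == "exponential":
                sv = self.amount * np.exp(-np.minimum(k * self.delay, 700.0))
            else:
                s = np.exp(tb[:, 2])
                sv = self.amount * np.exp(-np.minimum((k * self.delay) ** s, 700.0))
            with np.errstate(over="ignore"):  # expit maps +/-inf cleanly
                p = expit((sv - self.ss_amount) / beta)
        else:
            p = _itch_prob_arrays(self.amount, self.delay, self.ss_amount, 0.0, tb)
        p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
        return self.choice * np.log(p) + (1 - self.choice) * np.log1p(-p)

    def block_loglik(self, trial_ll: np.ndarray) -> np.ndarray:
        return np.bincount(self.trial_block, weights=trial_ll, minlength=self.n_blocks)


def _slice_sigma(sigma: float, n: float, resid2: float, tau: float,
                 rng: np.random.Generator, width: float = 1.0) -> float:
    """One slice-sampling update of a group SD on the log scale.

    Target: p(log sigma | theta, mu) with a HalfNormal(tau) prior on sigma,
    i.e. -n*log(sigma) - resid2/(2 sigma^2) - sigma^2/(2 tau^2) + log(sigma).
    Stepping-out followed by shrinkage (Neal's procedure).
    """

    def logf(ls: float) -> float:
        s2 = np.exp(2.0 * ls)
        return (1.0 - n) * ls - resid2 / (2.0 * s2) - s2 / (2.0 * tau**2)

    x0 = np.log(sigma)
    logy = logf(x0) - rng.exponential()
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(50):
        if logf(lo) < logy:
            break
        lo -= width
    for _ in range(50):
        if logf(hi) < logy:
            break
        hi += width
    for _ in range(100):
        x1 = lo + (hi - lo) * rng.random()
        if logf(x1) >= logy:
            return float(np.exp(x1))
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return float(sigma)


def _run_chain(problem: _Problem, config: HierarchyConfig, rng: np.random.Generator):
    """One adaptive Metropolis-within-Gibbs chain.

    Returns kept draws of (theta, mu, sigma, per-trial loglik).
    """
    B, P, C = problem.n_blocks, problem.n_params, problem.n_cells
    priors = np.array([config.prior_for(p) for p in config.param_names])  # (P, 3)
    m0, s0, tau = priors[:, 0], priors[:, 1], priors[:, 2]

    mu = m0[None, :] + 0.1 * rng.standard_normal((C, P))
    sigma = 0.5 * tau[None, :] * np.exp(0.2 * rng.standard_normal((C, P)))
    theta = mu[problem.block_cell] + 0.1 * rng.standard_normal((B, P))

    step_theta = np.full((B, P), 0.3)
    step_nc = np.full((C, P), 0.3)

    trial_ll = problem.trial_loglik(theta)
    block_ll = problem.block_loglik(trial_ll)
    cell_count = np.bincount(problem.block_cell, minlength=C).astype(float)

    n_iter = config.warmup + config.draws * config.thin
    keep_theta = np.empty((config.draws, B, P))
    keep_mu = np.empty((config.draws, C, P))
    keep_sigma = np.empty((config.draws, C, P))
    keep_ll = np.empty((config.draws, len(problem.choice)))

    for t in range(n_iter):
        adapting = t < config.warmup
        gamma = min(0.25, 2.0 / np.sqrt(t + 1)) if adapting else 0.0

        # --- individual blocks: single-site random-walk MH per parameter,
        # vectorized over blocks (conditionally independent given hypers)
        mu_b = mu[problem.block_cell]
        sig_b = sigma[problem.block_cell]
        for p_ in range(P):
            prop = theta.copy()
            prop[:, p_] += step_theta[:, p_] * rng.standard_normal(B)
            prop_trial_ll = problem.trial_loglik(prop)
            prop_block_ll = problem.block_loglik(prop_trial_ll)
            logprior_cur = -0.5 * ((theta[:, p_] - mu_b[:, p_]) / sig_b[:, p_]) ** 2
            logprior_prop = -0.5 * ((prop[:, p_] - mu_b[:, p_]) / sig_b[:, p_]) ** 2
            log_acc = (prop_block_ll + logprior_prop) - (block_ll + logprior_cur)
            accept = np.log(rng.random(B)) < log_acc
            theta[accept, p_] = prop[accept, p_]
            block_ll[accept] = prop_block_ll[accept]
            sel = accept[problem.trial_block]
            trial_ll[sel] = prop_trial_ll[sel]
            if adapting:
                step_theta[:, p_] *= np.exp(
                    gamma * (np.minimum(np.exp(log_acc), 1.0) - _ADAPT_TARGET)
                )

        # --- group means: exact conjugate normal conditional
        sums = np.zeros((C, P))
        for p_ in range(P):
            sums[:, p_] = np.bincount(problem.block_cell, weights=theta[:, p_], minlength=C)
        prec = 1.0 / s0[None, :] ** 2 + cell_count[:, None] / sigma**2
        mean = (m0[None, :] / s0[None, :] ** 2 + sums / sigma**2) / prec
        mu = mean + rng.standard_normal((C, P)) / np.sqrt(prec)

        # --- group SDs: slice sampling on log sigma; the conditional given
        # (theta, mu) is univariate and cheap, and slice moves are tuning-free
        resid2 = np.zeros((C, P))
        dev2 = (theta - mu[problem.block_cell]) ** 2
        for p_ in range(P):
            resid2[:, p_] = np.bincount(problem.block_cell, weights=dev2[:, p_], minlength=C)
        for c_ in range(C):
            for p_ in range(P):
                sigma[c_, p_] = _slice_sigma(
                    sigma[c_, p_], cell_count[c_], resid2[c_, p_], tau[p_], rng
                )

        # --- interweaving (non-centered) step: jointly move (mu, sigma) of a
        # cell with its individual parameters dragged along as standardized
        # residuals eta = (theta - mu)/sigma.  Breaks the funnel coupling that
        # slows centered updates when individual parameters are weakly
        # identified by the data.
        for p_ in range(P):
            eta = (theta[:, p_] - mu[problem.block_cell, p_]) / sigma[problem.block_cell, p_]
            sig_prop = sigma[:, p_] * np.exp(step_nc[:, p_] * rng.standard_normal(C))
            prop = theta.copy()
            prop[:, p_] = mu[problem.block_cell, p_] + sig_prop[problem.block_cell] * eta
            prop_trial_ll = problem.trial_loglik(prop)
            prop_block_ll = problem.block_loglik(prop_trial_ll)
            cell_ll_cur = np.bincount(problem.block_cell, weights=block_ll, minlength=C)
            cell_ll_prop = np.bincount(problem.block_cell, weights=prop_block_ll, minlength=C)
            log_acc_nc = (
                cell_ll_prop - cell_ll_cur
                - (sig_prop**2 - sigma[:, p_] ** 2) / (2.0 * tau[p_] ** 2)
                + np.log(sig_prop) - np.log(sigma[:, p_])  # log-scale proposal Jacobian
            )
            acc_nc = np.log(rng.random(C)) < log_acc_nc
            sigma[acc_nc, p_] = sig_prop[acc_nc]
            blk_acc = acc_nc[problem.block_cell]
            theta[blk_acc, p_] = prop[blk_acc, p_]
            block_ll[blk_acc] = prop_block_ll[blk_acc]
            sel = blk_acc[problem.trial_block]
            trial_ll[sel] = prop_trial_ll[sel]
            if adapting:
                step_nc[:, p_] *= np.exp(
                    gamma * (np.minimum(np.exp(log_acc_nc), 1.0) - _ADAPT_TARGET)
                )

        post = t - config.warmup
        if post >= 0 and (post + 1) % config.thin == 0:
            i = post // config.thin
            keep_theta[i] = theta
            keep_mu[i] = mu
            keep_sigma[i] = sigma
            keep_ll[i] = trial_ll

    return keep_theta, keep_mu, keep_sigma, keep_ll


def fit_hierarchical(dataset: ChoiceDataset, config: HierarchyConfig) -> PosteriorDraws:
    """Fit the hierarchical choice model by MCMC.

    Runs ``config.chains`` independent chains (seeded off ``config.seed``
    via numpy's SeedSequence, so results are reproducible run-to-run) and
    gates convergence on split R-hat and bulk ESS.  A non-converged fit is
    returned with ``converged=False`` and explicit warnings, never silently.
    """
    problem = _Problem(dataset, config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    out = [_run_chain(problem, config, np.random.default_rng(s)) for s in seeds]
    theta = np.stack([o[0] for o in out])
    mu = np.stack([o[1] for o in out])
    sigma = np.stack([o[2] for o in out])
    loglik = np.stack([o[3] for o in out])

    diag_rows = []
    warn: List[str] = []
    for j, name in enumerate(config.param_names):
        for label, arr, idx_names in (
            (name, theta[..., j], problem.block_participant),
            (f"mu_{name}", mu[..., j], problem.cell_labels),
            (f"sigma_{name}", sigma[..., j], problem.cell_labels),
        ):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                rhat = np.atleast_1d(np.asarray(az.rhat(az.convert_to_dataset(arr))["x"]))
                ess = np.atleast_1d(np.asarray(az.ess(az.convert_to_dataset(arr))["x"]))
            for i in range(arr.shape[-1]):
                diag_rows.append({
                    "parameter": label, "element": str(idx_names[i]),
                    "rhat": float(rhat[i]), "ess_bulk": float(ess[i]),
                })
    diagnostics = pd.DataFrame(diag_rows)
    bad_rhat = diagnostics[diagnostics["rhat"] > config.rhat_max]
    bad_ess = diagnostics[diagnostics["ess_bulk"] < config.ess_min]
    if len(bad_rhat):
        warn.append(
            f"{len(bad_rhat)} parameters exceed R-hat {config.rhat_max} "
            f"(worst {bad_rhat['rhat'].max():.3f})"
        )
    if len(bad_ess):
        warn.append(
            f"{len(bad_ess)} parameters below ESS {config.ess_min:.0f} "
            f"(worst {bad_ess['ess_bulk'].min():.0f})"
        )
    for w in warn:
        _warnings.warn(w, stacklevel=2)

    return PosteriorDraws(
        theta=theta, mu=mu, sigma=sigma, loglik=loglik,
        param_names=config.param_names,
        block_participant=problem.block_participant,
        block_condition=problem.block_condition,
        block_group=problem.block_group,
        cell_labels=problem.cell_labels,
        diagnostics=diagnostics, converged=not warn, warnings=warn,
        config=config, seed=config.seed,
    )


def point_estimates(draws: PosteriorDraws, estimator: str = "posterior_mean") -> pd.DataFrame:
    """Per-participant, per-condition point estimates of all sampled parameters.

    ``posterior_median`` uses the numpy convention: the midpoint of the two
    central order statistics when the draw count is even.
    """
    if estimator == "posterior_mean":
        agg = np.mean
    elif estimator == "posterior_median":
        agg = np.median
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    rows = {
        "participant_id": draws.block_participant,
        "group": draws.block_group,
        "condition": draws.block_condition,
    }
    for name in draws.param_names:
        rows[name] = agg(draws.param_draws(name), axis=0)
    return pd.DataFrame(rows)


def recompute_loglik(draws: PosteriorDraws, dataset: ChoiceDataset) -> np.ndarray:
    """Recompute the trials-by-samples log-likelihood matrix from stored draws.

    Cross-check for the matrix accumulated during sampling.
    """
    problem = _Problem(dataset, draws.config)
    c, d, b, p = draws.theta.shape
    flat = draws.theta.reshape(c * d, b, p)
    out = np.empty((len(problem.choice), c * d))
    for s in range(c * d):
        out[:, s] = problem.trial_loglik(flat[s])
    return out


def fit_individual_mle(
    dataset: ChoiceDataset,
    model: str = "hyperbolic",
    log_k_bounds: Tuple[float, float] = (np.log(1e-5), np.log(1.0)),
    log_beta_bounds: Tuple[float, float] = (np.log(0.05), np.log(50.0)),
) -> pd.DataFrame:
    """Independent per-participant, per-condition maximum-likelihood fits.

    No pooling: each participant x condition cell is optimized separately
    (L-BFGS-B on the clamped Bernoulli log-likelihood).  Mainly a baseline
    against which hierarchical shrinkage can be demonstrated, and the
    engine behind the pretest estimator.
    """
    if model not in VALUE_MODELS:
        raise ValueError("individual MLE supports the value-based models only")
    rows = []
    for (pid, cond), sub in dataset.trials.groupby(
        ["participant_id", "condition"], sort=False
    ):
        amount = sub["amount_ll"].to_numpy(float)
        delay = sub["delay_days"].to_numpy(float)
        choice = sub["choice_ll"].to_numpy(int)

        def nll(x):
            k, beta = np.exp(x[0]), np.exp(x[1])
            if model == "hyperbolic":
                sv = amount / (1.0 + k * delay)
            elif model == "exponential":
                sv = amount * np.exp(-np.minimum(k * delay, 700.0))
            else:
                s = np.exp(x[2])
                sv = amount * np.exp(-np.minimum((k * delay) ** s, 700.0))
            p = np.clip(expit((sv - 20.0) / beta), PROB_FLOOR, 1 - PROB_FLOOR)
            return -np.sum(choice * np.log(p) + (1 - choice) * np.log1p(-p))

        x0 = [-4.5, 0.7] + ([0.0] if model == "constant_sensitivity" else [])
        bounds = [log_k_bounds, log_beta_bounds] + (
            [(-2.0, 2.0)] if model == "constant_sensitivity" else []
        )
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        row = {"participant_id": pid, "group": str(sub["group"].iloc[0]),
               "condition": cond, "log_k": res.x[0], "log_beta": res.x[1]}
        if model == "constant_sensitivity":
            row["log_s"] = res.x[2]
        rows.append(row)
    return pd.DataFrame(rows)
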