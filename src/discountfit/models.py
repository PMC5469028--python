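"""Discount functions, the softmax choice rule, and pointwise choice likelihoods.

Four candidate valuation/choice models for intertemporal choice between a
fixed smaller-sooner (SS) amount available immediately and a larger-later
(LL) amount at a delay of ``D`` days:

``hyperbolic``
    SV = A / (1 + k*D) with discount rate ``k`` per day.  Larger ``k``
    means steeper devaluation of delayed rewards (higher impulsivity).
``exponential``
    SV = A * exp(-k*D), the classical discounted-utility form.
``constant_sensitivity``
    SV = A * exp(-(k*D)**s); the exponent ``s`` bends the time axis and the
    form reduces to the exponential model at ``s = 1``.
``itch``
    The intertemporal choice heuristic: no subjective value at all, but a
    direct logistic choice rule on absolute and relative amount and delay
    differences between the two options.

The three value-based models are mapped onto a binary choice through a
softmax (two-option logistic) with temperature ``beta`` in euros: the larger
``beta``, the noisier the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "Offer",
    "DiscountParams",
    "ChoicePolicy",
    "ItchWeights",
    "VALUE_MODELS",
    "MODELS",
    "sv_hyperbolic",
    "sv_exponential",
    "sv_constant_sensitivity",
    "subjective_value",
    "p_choose_ll_softmax",
    "p_choose_ll_itch",
    "indifference_amount",
    "choice_probability",
    "pointwise_loglik",
    "PROB_FLOOR",
]

#: Models with a scalar subjective value and a softmax policy.
VALUE_MODELS = ("hyperbolic", "exponential", "constant_sensitivity")
#: All supported models.
MODELS = VALUE_MODELS + ("itch",)

#: Choice probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR] before
#: taking logs so the pointwise log-likelihood stays finite under extreme
#: parameter draws.
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class Offer:
    """One intertemporal choice problem.

    The study design holds the smaller-sooner option fixed at 20 euros now;
    the larger-later option varies in amount and delay, optionally carrying
    an episodic event tag in the episodic condition.
    """

    amount_ll: float
    delay_ll: float
    amount_ss: float = 20.0
    delay_ss: float = 0.0
    condition: str = "control"
    tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.amount_ll <= 0 or self.amount_ss <= 0:
            raise ValueError("offer amounts must be positive")
        if self.delay_ll < 0:
            raise ValueError("LL delay must be nonnegative")
        if self.delay_ss != 0.0:
            raise ValueError("the SS option is immediate (delay_ss = 0) in this design")
        if self.condition not in ("control", "episodic"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class ItchWeights:
    """Weights of the intertemporal choice heuristic's logistic rule.

    logit p(LL) = intercept
                  + w_amount_abs * (A_ll - A_ss)
                  + w_amount_rel * (A_ll - A_ss) / mean(A_ll, A_ss)
                  + w_delay_abs  * (D_ll - D_ss)
                  + w_delay_rel  * (D_ll - D_ss) / mean(D_ll, D_ss)

    The relative-delay term uses max(mean delay, 1) so an immediate SS option
    cannot zero the denominator.
    """

    intercept: float = 0.0
    w_amount_abs: float = 0.0
    w_amount_rel: float = 0.0
    w_delay_abs: float = 0.0
    w_delay_rel: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.intercept, self.w_amount_abs, self.w_amount_rel,
             self.w_delay_abs, self.w_delay_rel],
            dtype=float,
        )


@dataclass(frozen=True)
class DiscountParams:
    """Parameters of one valuation model for one participant and condition."""

    model: str
    k: Optional[float] = None
    s: Optional[float] = None
    itch_weights: Optional[ItchWeights] = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model in VALUE_MODELS:
            if self.k is None or self.k <= 0:
                raise ValueError(f"{self.model} requires k > 0")
            if self.model == "constant_sensitivity":
                if self.s is None or self.s <= 0:
                    raise ValueError("constant_sensitivity requires s > 0")
            elif self.s is not None:
                raise ValueError(f"{self.model} takes no sensitivity exponent")
            if self.itch_weights is not None:
                raise ValueError("itch_weights only apply to the itch model")
        else:  # itch
            if self.itch_weights is None:
                raise ValueError("itch requires itch_weights")
            if self.k is not None or self.s is not None:
                raise ValueError("itch takes no k or s")


@dataclass(frozen=True)
class ChoicePolicy:
    """Softmax decision rule with temperature ``beta`` (euros)."""

    beta: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def _check_value_args(amount, delay, k) -> None:
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(amount <= 0):
        raise ValueError("amount must be positive")
    if np.any(delay < 0):
        raise ValueError("delay must be nonnegative")
    if np.any(k <= 0):
        raise ValueError("discount rate k must be positive")


def sv_hyperbolic(amount, delay, k):
    """Hyperbolic subjective value SV = A / (1 + k*D).

    Parameters are broadcast; amounts in euros, delays in days, ``k`` per day.
    """
    _check_value_args(amount, delay, k)
    return np.asarray(amount, float) / (1.0 + np.asarray(k, float) * np.asarray(delay, float))


def sv_exponential(amount, delay, k):
    """Exponential (discounted-utility) subjective value SV = A * exp(-k*D)."""
    _check_value_args(amount, delay, k)
    return np.asarray(amount, float) * np.exp(-np.asarray(k, float) * np.asarray(delay, float))


def sv_constant_sensitivity(amount, delay, k, s):
    """Constant-sensitivity subjective value SV = A * exp(-(k*D)**s).

    Reduces to :func:`sv_exponential` at ``s = 1``.
    """
    _check_value_args(amount, delay, k)
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("sensitivity exponent s must be positive")
    kd = np.asarray(k, float) * np.asarray(delay, float)
    return np.asarray(amount, float) * np.exp(-np.power(kd, s))


def subjective_value(model: str, amount, delay, k, s=None):
    """Dispatch to the named value model's SV function."""
    if model == "hyperbolic":
        return sv_hyperbolic(amount, delay, k)
    if model == "exponential":
        return sv_exponential(amount, delay, k)
    if model == "constant_sensitivity":
        return sv_constant_sensitivity(amount, delay, k, s)
    raise ValueError(f"{model!r} is not a value-based model")


def p_choose_ll_softmax(sv_ll, sv_ss, beta):
    """Softmax probability of choosing the larger-later option.

    Mathematically exp(sv_ll/b) / (exp(sv_ss/b) + exp(sv_ll/b)); computed as
    the logistic of (sv_ll - sv_ss)/beta, which is the same quantity but does
    not overflow for small ``beta``.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    return expit((np.asarray(sv_ll, float) - np.asarray(sv_ss, float)) / beta)


def p_choose_ll_itch(offer: Offer, weights: ItchWeights) -> float:
    """Choice probability under the intertemporal choice heuristic."""
    if not isinstance(weights, ItchWeights):
        raise ValueError("weights must be an ItchWeights instance")
    return float(
        _itch_prob_arrays(
            np.atleast_1d(offer.amount_ll), np.atleast_1d(offer.delay_ll),
            offer.amount_ss, offer.delay_ss, weights.as_array(),
        )[0]
    )


def _itch_prob_arrays(amount_ll, delay_ll, amount_ss, delay_ss, w) -> np.ndarray:
    """Vectorized ITCH probability; ``w`` rows broadcast against trials.

    ``w`` has last axis [intercept, amount_abs, amount_rel, delay_abs, delay_rel].
    """
    da = amount_ll - amount_ss
    dr = da / (0.5 * (amount_ll + amount_ss))
    dt = delay_ll - delay_ss
    tr = dt / np.maximum(0.5 * (delay_ll + delay_ss), 1.0)
    logit = (
        w[..., 0] + w[..., 1] * da + w[..., 2] * dr + w[..., 3] * dt + w[..., 4] * tr
    )
    return expit(logit)


def indifference_amount(k, delay, ss_amount=20.0):
    """LL amount whose hyperbolic SV equals the SS amount: A* = SS * (1 + k*D)."""
    _check_value_args(ss_amount, delay, k)
    return np.asarray(ss_amount, float) * (1.0 + np.asarray(k, float) * np.asarray(delay, float))


def choice_probability(params: DiscountParams, policy: Optional[ChoicePolicy],
                       amount_ll, delay_days, ss_amount=20.0):
    """P(choose LL) for one parameter set over arrays of offers.

    Value-based models require a ``policy``; the ITCH model ignores it.
    """
    if params.model in VALUE_MODELS:
        if policy is None:
            raise ValueError(f"{params.model} requires a ChoicePolicy")
        sv = subjective_value(params.model, amount_ll, delay_days, params.k, params.s)
        return p_choose_ll_softmax(sv, ss_amount, policy.beta)
    return _itch_prob_arrays(
        np.asarray(amount_ll, float), np.asarray(delay_days, float),
        float(ss_amount), 0.0, params.itch_weights.as_array(),
    )


def pointwise_loglik(
    dataset,
    params: dict,
    policies: Optional[dict] = None,
    ss_amount: float = 20.0,
) -> np.ndarray:
    """Per-trial Bernoulli log-likelihood of the observed choices.

    Parameters
    ----------
    dataset : ChoiceDataset
        The observed trials.
    params : dict
        Maps ``(participant_id, condition)`` to a :class:`DiscountParams`.
    policies : dict, optional
        Maps ``(participant_id, condition)`` to a :class:`ChoicePolicy`;
        required for the value-based models.

    Returns
    -------
    numpy.ndarray
        One log-likelihood per trial, in the dataset's trial order (one
        column of the trials-by-samples matrix an MCMC fit accumulates).
    """
    df = dataset.trials
    out = np.empty(len(df), dtype=float)
    for (pid, cond), sub in df.groupby(["participant_id", "condition"], sort=False):
        key = (pid, cond)
        if key not in params:
            raise KeyError(f"no parameters for participant {pid!r}, condition {cond!r}")
        pol = None
        if params[key].model in VALUE_MODELS:
            if policies is None or key not in policies:
                raise KeyError(f"no choice policy for participant {pid!r}, condition {cond!r}")
            pol = policies[key]
        p = choice_probability(
            params[key], pol,
            sub["amount_ll"].to_numpy(), sub["delay_days"].to_numpy(), ss_amount,
        )
        p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
        y = sub["choice_ll"].to_numpy()
        out[sub.index.to_numpy()] = y * np.log(p) + (1 - y) * np.log1p(-p)
    return out
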