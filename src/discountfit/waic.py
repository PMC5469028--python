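"""WAIC model comparison from a trials-by-samples pointwise log-likelihood matrix.

The widely applicable (Watanabe-Akaike) information criterion estimates
out-of-sample predictive fit from within-sample posterior draws:

    lppd   = sum_i log( mean_s exp(ll[i, s]) )
    p_waic = sum_i var_s( ll[i, s] )            (sample variance, n-1)
    WAIC   = -2 * (lppd - p_waic)               (deviance scale; lower is better)

where ``ll[i, s]`` is the log-likelihood of trial *i* under posterior
sample *s*.  The variance form of the effective-parameter penalty is used,
and the lppd inner mean is computed with a log-sum-exp guard so strongly
negative log-likelihoods do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["WaicResult", "compute_waic", "rank_models"]


@dataclass(frozen=True)
class WaicResult:
    """The three WAIC components for one fitted model."""

    lppd: float
    p_waic: float
    waic: float
    n_trials: int
    n_samples: int


def compute_waic(loglik: np.ndarray) -> WaicResult:
    """Compute WAIC from a (trials x samples) pointwise log-likelihood matrix.

    A single-sample matrix has zero penalty by construction, so its WAIC is
    just the deviance of that sample.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 1 or ll.shape[1] < 1:
        raise ValueError("loglik must be a (trials x samples) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik contains non-finite entries")
    n, s = ll.shape
    lppd = float(np.sum(logsumexp(ll, axis=1) - np.log(s)))
    p_waic = float(np.sum(np.var(ll, axis=1, ddof=1))) if s > 1 else 0.0
    return WaicResult(
        lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic),
        n_trials=n, n_samples=s,
    )


def rank_models(results: Sequence[Tuple[str, WaicResult]]) -> pd.DataFrame:
    """Rank candidate models by WAIC (ascending; lower predicts better).

    Returns a table with columns ``model, waic, lppd, p_waic, delta_waic``;
    the best model has ``delta_waic = 0``.
    """
    if len(results) < 2:
        raise ValueError("ranking needs at least two models")
    names = [name for name, _ in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate model names in {names}")
    df = pd.DataFrame(
        {
            "model": names,
            "waic": [r.waic for _, r in results],
            "lppd": [r.lppd for _, r in results],
            "p_waic": [r.p_waic for _, r in results],
        }
    ).sort_values("waic", kind="mergesort").reset_index(drop=True)
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    return df
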