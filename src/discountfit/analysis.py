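"""Group-level behavioral statistics on fitted discounting parameters.

Works on a wide per-participant table (one row per participant with
``log(k)`` and ``log(beta)`` for each condition plus optional covariates)
and reproduces the standard analysis battery for an episodic-tagging
study: the per-participant tag-effect (reduction in log discount rate
under episodic tags), a two-way mixed ANOVA (group between, condition
within), an addiction-severity composite and its one-sided correlation
with baseline discounting, a multiple regression explaining tag-effect
variability, and a 2x2 proportion comparison of who improved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "participant_table",
    "tag_effect",
    "severity_score",
    "group_condition_anova",
    "severity_correlation",
    "tag_effect_regression",
    "proportion_comparison",
    "welch_ttest",
]


def participant_table(estimates: pd.DataFrame,
                      covariates: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Pivot a long per-participant x condition estimate table to wide form.

    ``estimates`` is the output of hierarchical point estimation (columns
    ``participant_id, group, condition, log_k, log_beta``); the result has
    one row per participant with ``logk_control, logk_episodic,
    logbeta_control, logbeta_episodic``, joined with ``covariates`` on
    ``participant_id`` when given.
    """
    wide = estimates.pivot_table(
        index=["participant_id", "group"], columns="condition",
        values=["log_k", "log_beta"], aggfunc="first",
    )
    wide.columns = [f"{'logk' if v == 'log_k' else 'logbeta'}_{c}" for v, c in wide.columns]
    wide = wide.reset_index()
    if covariates is not None:
        wide = wide.merge(covariates, on="participant_id", how="left")
    return wide


def _require_conditions(table: pd.DataFrame) -> None:
    for col in ("logk_control", "logk_episodic"):
        if col not in table.columns:
            raise ValueError(f"participant table lacks column {col!r}")
        if table[col].isna().any():
            bad = table.loc[table[col].isna(), "participant_id"].tolist()
            raise ValueError(f"missing {col} for participants {bad}")


def tag_effect(table: pd.DataFrame) -> pd.Series:
    """Per-participant tag-effect: log(k)_control - log(k)_episodic.

    Positive values mean shallower discounting (less impulsivity) under
    episodic tags.
    """
    _require_conditions(table)
    eff = table["logk_control"] - table["logk_episodic"]
    eff.name = "tag_effect"
    return eff


def severity_score(kfg, sogs, cohort_kfg, cohort_sogs) -> np.ndarray:
    """Composite addiction severity: mean of within-cohort z-scores.

    Each instrument (e.g. two gambling questionnaires) is z-scaled against
    its cohort vector; the composite is the average of the two z-scores.
    """
    cohort_kfg = np.asarray(cohort_kfg, float)
    cohort_sogs = np.asarray(cohort_sogs, float)
    sd_k, sd_s = cohort_kfg.std(ddof=1), cohort_sogs.std(ddof=1)
    if sd_k == 0 or sd_s == 0:
        raise ValueError("zero-variance cohort vector; cannot z-scale")
    z1 = (np.asarray(kfg, float) - cohort_kfg.mean()) / sd_k
    z2 = (np.asarray(sogs, float) - cohort_sogs.mean()) / sd_s
    return 0.5 * (z1 + z2)


def _mixed_anova_core(y: np.ndarray, group: np.ndarray) -> pd.DataFrame:
    """Two-way mixed ANOVA, a groups between x 2 conditions within.

    ``y`` is (N participants, 2 conditions); classical partitioning with
    participant as the within-subject blocking factor and weighted
    (cell-size) marginal means.
    """
    n_total, b = y.shape
    labels, g_idx = np.unique(group, return_inverse=True)
    a = len(labels)
    if np.bincount(g_idx).min() < 2:
        raise ValueError("need at least 2 participants per group")
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    n_j = np.bincount(g_idx).astype(float)
    group_mean = np.array([y[g_idx == j].mean() for j in range(a)])
    cell_mean = np.array([y[g_idx == j].mean(axis=0) for j in range(a)])  # (a, b)

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = b * float(((subj_mean - grand) ** 2).sum())
    ss_group = b * float((n_j * (group_mean - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = n_total * float(((cond_mean - grand) ** 2).sum())
    ss_inter = float(
        (n_j[:, None] * (cell_mean - group_mean[:, None] - cond_mean[None, :] + grand) ** 2).sum()
    )
    ss_within_subj = ss_total - ss_between_subj
    ss_cond_err = ss_within_subj - ss_cond - ss_inter

    df_group, df_subj = a - 1, n_total - a
    df_cond, df_inter = b - 1, (a - 1) * (b - 1)
    df_cond_err = (n_total - a) * (b - 1)

    rows = []
    tiny = 1e-12 * max(ss_total, 1.0)  # fp residue floor for degenerate data
    for name, ss, df1, ss_err, df2 in (
        ("group", ss_group, df_group, ss_subj_within, df_subj),
        ("condition", ss_cond, df_cond, ss_cond_err, df_cond_err),
        ("interaction", ss_inter, df_inter, ss_cond_err, df_cond_err),
    ):
        ms, ms_err = ss / df1, ss_err / df2
        if ss_err > tiny:
            f = ms / ms_err
        else:  # degenerate data: no within-cell error at all
            f = 0.0 if ss <= tiny else np.inf
        p = stats.f.sf(f, df1, df2) if np.isfinite(f) else 0.0
        rows.append({"effect": name, "ss": ss, "df1": df1, "df2": df2,
                     "F": f, "p": p})
    return pd.DataFrame(rows)


def group_condition_anova(table: pd.DataFrame, value: str = "logk") -> pd.DataFrame:
    """Mixed two-way ANOVA of log(k) (or log(beta)): group x condition.

    Group (e.g. gamblers vs. controls) is between-subject, condition
    (episodic vs. control) within-subject.  Returns F, dfs and p for the
    group and condition main effects and their interaction.
    """
    cols = [f"{value}_control", f"{value}_episodic"]
    for c in cols:
        if c not in table.columns:
            raise ValueError(f"participant table lacks column {c!r}")
    if table[cols].isna().any().any():
        raise ValueError("missing condition cells; mixed ANOVA requires complete rows")
    y = table[cols].to_numpy(float)
    return _mixed_anova_core(y, table["group"].to_numpy())


def severity_correlation(table: pd.DataFrame, group: str = "gambler") -> Tuple[float, float]:
    """Pearson correlation of control-condition log(k) with addiction severity.

    Restricted to the given group; the p-value is one-sided for a positive
    association (steeper baseline discounting in more severe gambling).
    """
    sub = table[table["group"] == group]
    if "severity" not in sub.columns:
        raise ValueError("participant table lacks a 'severity' column")
    sub = sub.dropna(subset=["severity", "logk_control"])
    if len(sub) < 3:
        raise ValueError("need at least 3 participants with severity scores")
    x = sub["logk_control"].to_numpy(float)
    y = sub["severity"].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector; correlation undefined")
    res = stats.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


#: Predictors of the tag-effect regression (joined on the participant table).
TAG_EFFECT_PREDICTORS = (
    "group", "age", "education_years", "income", "ftnd", "audit", "bdi",
    "imagery", "logk_control",
)


def tag_effect_regression(table: pd.DataFrame,
                          predictors: Sequence[str] = TAG_EFFECT_PREDICTORS,
                          severity_bdi_interaction: bool = True) -> pd.DataFrame:
    """OLS regression of the per-participant tag-effect on covariates.

    Default predictors: group, age, education, income, nicotine (FTND),
    alcohol (AUDIT), depression (BDI), post-scan imagery, and baseline
    (control-condition) log(k); plus the severity x BDI interaction.
    Returns a coefficient table (coef, SE, t, p).  Collinear design
    columns raise a rank-deficiency error naming the offenders.
    """
    y = tag_effect(table).to_numpy(float)
    X = pd.DataFrame(index=table.index)
    for col in predictors:
        if col not in table.columns:
            raise ValueError(f"predictor column {col!r} missing from table")
        if col == "group":
            X["group"] = (table["group"] == "gambler").astype(float)
        else:
            X[col] = pd.to_numeric(table[col], errors="raise")
    if severity_bdi_interaction:
        for col in ("severity", "bdi"):
            if col not in table.columns:
                raise ValueError(f"interaction requires column {col!r}")
        sev = pd.to_numeric(table["severity"], errors="raise")
        if sev.isna().any():
            raise ValueError("severity has missing values; cannot form the interaction")
        X["severity"] = sev
        X["severity_x_bdi"] = sev * pd.to_numeric(table["bdi"], errors="raise")
    if len(table) <= X.shape[1] + 1:
        raise ValueError(
            f"n = {len(table)} participants cannot support {X.shape[1]} predictors"
        )
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        dup = [
            (X.columns[i], X.columns[j])
            for i in range(len(X.columns)) for j in range(i + 1, len(X.columns))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {dup or 'unknown'}")
    fit = sm.OLS(y, Xc).fit()
    return pd.DataFrame({
        "predictor": Xc.columns, "coef": fit.params, "se": fit.bse,
        "t": fit.tvalues, "p": fit.pvalues,
    }).reset_index(drop=True)


def proportion_comparison(n_improved_a: int, n_a: int, n_improved_b: int, n_b: int,
                          continuity_correction: bool = True) -> Tuple[float, float]:
    """2x2 chi-square test of equal improvement proportions between groups.

    "Improved" means a lower discount rate in the episodic condition.
    Yates continuity correction is on by default (configurable).
    """
    for imp, tot in ((n_improved_a, n_a), (n_improved_b, n_b)):
        if tot <= 0:
            raise ValueError("group totals must be positive")
        if not 0 <= imp <= tot:
            raise ValueError("improved counts must lie in [0, total]")
    obs = np.array([[n_improved_a, n_a - n_improved_a],
                    [n_improved_b, n_b - n_improved_b]], dtype=float)
    if obs[:, 0].sum() == 0 or obs[:, 1].sum() == 0:
        # all improved or none improved: proportions trivially equal
        return 0.0, 1.0
    res = stats.chi2_contingency(obs, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def welch_ttest(a, b) -> Tuple[float, float, float]:
    """Unequal-variance (Welch) t-test for demographic group comparisons.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
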