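"""Group statistics: mixed two-factor repeated-measures ANOVA, pooled
two-sample t-test and mean +/- SEM summaries with normal-approximation 95%
confidence bands.

The ANOVA is the classical mixed between-within decomposition (one
between-subject factor, e.g. patient group, crossed with one within-subject
factor, e.g. stimulus intensity or tone frequency), computed directly from
sums of squares.  The design must be balanced across the within factor; the
sampling unit defaults to the ear, with subject-level means available by
passing a subject column aggregated beforehand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def rm_anova_two_factor(table: pd.DataFrame, subject: str = "subject",
                        group: str = "group", within: str = "level",
                        value: str = "value") -> dict:
    """Mixed-design ANOVA with one between and one within factor.

    ``table`` is long-form with one row per (sampling unit, within level).
    Every unit must appear exactly once at every within level and belong to
    exactly one group (unbalanced or missing cells raise ``ValueError``).

    Returns the three F tests (group, within, interaction) with their
    degrees of freedom and p-values, plus every sum-of-squares term of the
    decomposition::

        SS_total = SS_group + SS_subj_within_group
                 + SS_within + SS_interaction + SS_error
    """
    df = table[[subject, group, within, value]].copy()
    wide = df.pivot_table(index=[subject, group], columns=within,
                          values=value, aggfunc="count")
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError("design must be balanced: every subject needs "
                         "exactly one observation at every within level")
    groups_per_subject = df.groupby(subject)[group].nunique()
    if (groups_per_subject != 1).any():
        raise ValueError("each subject must belong to exactly one group")

    data = df.pivot_table(index=[subject, group], columns=within,
                          values=value)
    x = data.to_numpy(dtype=float)              # (n_subjects, b levels)
    group_of = data.index.get_level_values(1).to_numpy()
    group_labels = pd.unique(group_of)
    a, b = len(group_labels), x.shape[1]
    n_subj = x.shape[0]
    if a < 2 or b < 2:
        raise ValueError("need >= 2 groups and >= 2 within levels")
    n_per_group = pd.Series(group_of).value_counts()
    if n_per_group.nunique() != 1:
        raise ValueError("groups must be of equal size in the v1 balanced "
                         "design")
    n = int(n_per_group.iloc[0])

    grand = x.mean()
    subj_means = x.mean(axis=1)
    level_means = x.mean(axis=0)
    group_means = np.array([x[group_of == g].mean() for g in group_labels])
    cell_means = np.array([x[group_of == g].mean(axis=0)
                           for g in group_labels])   # (a, b)

    ss_total = float(((x - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    # referencing the group means to their own mean (equal under balance)
    # makes SS_group exactly zero when the group means are identical
    ss_group = float(n * b * ((group_means - group_means.mean()) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_within_factor = float(a * n * ((level_means - grand) ** 2).sum())
    ss_interaction = float(n * ((cell_means - group_means[:, None]
                                 - level_means[None, :] + grand) ** 2).sum())
    ss_error = ss_total - ss_between_subj - ss_within_factor - ss_interaction

    df_group = a - 1
    df_subj = n_subj - a
    df_within = b - 1
    df_interaction = (a - 1) * (b - 1)
    df_error = df_subj * (b - 1)

    def f_and_p(ss_num, df_num, ss_den, df_den):
        ms_den = ss_den / df_den
        ms_num = ss_num / df_num
        if ms_den == 0.0:
            f = 0.0 if ms_num == 0.0 else float("inf")
        else:
            f = ms_num / ms_den
        p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
        return f, p

    f_group, p_group = f_and_p(ss_group, df_group, ss_subj_within, df_subj)
    f_within, p_within = f_and_p(ss_within_factor, df_within,
                                 ss_error, df_error)
    f_inter, p_inter = f_and_p(ss_interaction, df_interaction,
                               ss_error, df_error)
    return {
        "F_group": f_group, "p_group": p_group,
        "df_group": (df_group, df_subj),
        "F_within": f_within, "p_within": p_within,
        "df_within": (df_within, df_error),
        "F_interaction": f_inter, "p_interaction": p_inter,
        "df_interaction": (df_interaction, df_error),
        "ss": {"total": ss_total, "group": ss_group,
               "subj_within_group": ss_subj_within,
               "within": ss_within_factor, "interaction": ss_interaction,
               "error": ss_error},
    }


def two_sample_t(x, y) -> dict:
    """Pooled-variance two-sided two-sample t-test.

    Degenerate inputs: zero pooled variance with equal means gives t = 0
    (p = 1); zero pooled variance with unequal means gives an infinite t
    (p = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
    else:
        t = diff / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return {"t": float(t), "p": p, "df": df}


def summarize_with_ci(table: pd.DataFrame, by, value: str = "value",
                      z: float = 1.96) -> pd.DataFrame:
    """Mean, SEM and normal-approximation 95% CI per cell.

    ``by`` is the grouping column (or list of columns).  Cells with n < 2
    get ``NaN`` SEM and CI bounds.
    """
    def agg(v):
        v = v.dropna()
        m = v.mean()
        sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) >= 2 else np.nan
        return pd.Series({"n": len(v), "mean": m, "sem": sem,
                          "ci_low": m - z * sem, "ci_high": m + z * sem})

    out = table.groupby(by)[value].apply(agg).unstack()
    out["n"] = out["n"].astype(int)
    return out.reset_index()
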