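"""Statistical layer for the mapping and nanostructure tables.

Thin, auditable wrappers around standard procedures: two-way ANOVA
(genotype × region) on subject-level regional means, Šidák or Tukey
post-hoc comparisons, Pearson's chi-squared on subtype frequency tables,
two-sample t-tests, Pearson correlation and Shapiro-Wilk normality.

Note on naming: the post-hoc option written "Sulak's" in some lab
protocols is interpreted here as the Šidák correction — no test of that
name exists, and Šidák is the standard multi-group companion to Tukey in
common statistics packages.  Reports printed by this module state the
interpretation explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "two_way_anova",
    "posthoc_pairwise",
    "chi_squared",
    "two_sample_t",
    "pearson_correlation",
    "shapiro_wilk",
]

SIDAK_NOTE = (
    "post-hoc method 'sidak': Šidák family-wise correction "
    "(the spelling 'Sulak' in source protocols is read as Šidák)"
)


@dataclass
class StatResult:
    """One test outcome: statistic, degrees of freedom, p, and extras."""

    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    direction: Optional[str] = None
    table: Optional[pd.DataFrame] = None
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def __str__(self) -> str:  # compact report line
        dof = ", ".join(f"{d:g}" for d in self.df)
        return f"{self.test_name}({dof}) = {self.statistic:.4g}, p = {self.p_value:.4g}"


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str = "genotype",
    factor_b: str = "region",
) -> dict[str, StatResult]:
    """Two-way ANOVA with interaction on a tidy table.

    One row per observation (one subject-level regional mean in the
    mapping analysis).  Uses type-II sums of squares; F for an effect with
    zero sum of squares is reported as 0 with p = 1 (e.g. noise-free
    identical cells).  Returns results keyed by factor_a, factor_b and
    "interaction".
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data[[value, factor_a, factor_b]].dropna().copy()
    for fac in (factor_a, factor_b):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    cells = df.groupby([factor_a, factor_b], observed=True).size().unstack(fill_value=0)
    empty = [
        (a, b)
        for a in cells.index
        for b in cells.columns
        if cells.loc[a, b] == 0
    ]
    if empty:
        raise ValueError(f"empty design cells make the interaction inestimable: {empty}")
    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    table = anova_lm(model, typ=2)
    keys = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": "interaction",
    }
    df_resid = float(table.loc["Residual", "df"])
    total_ss = float(table["sum_sq"].sum())
    results: dict[str, StatResult] = {}
    for row_key, name in keys.items():
        ss = float(table.loc[row_key, "sum_sq"])
        dfe = float(table.loc[row_key, "df"])
        f_val = float(table.loc[row_key, "F"])
        p_val = float(table.loc[row_key, "PR(>F)"])
        # an effect with (numerically) zero sum of squares has F = 0 by
        # definition, even when the residual SS is also zero
        if ss <= 1e-12 * max(total_ss, 1.0) or not np.isfinite(f_val):
            f_val, p_val = 0.0, 1.0
        results[name] = StatResult(
            test_name=f"two_way_anova[{name}]",
            statistic=f_val,
            df=(dfe, df_resid),
            p_value=p_val,
            table=table,
        )
    return results


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    nx, ny = len(x), len(y)
    dof = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / dof
    if sp2 == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), dof)
    return float(t), float(dof), float(p)


def posthoc_pairwise(
    data: pd.DataFrame,
    value: str,
    group: str,
    method: str = "sidak",
) -> StatResult:
    """All pairwise group comparisons with family-wise adjusted p-values.

    ``sidak``: pooled-variance t-test per pair, adjusted 1 − (1 − p)^m
    over the m pairs.  ``tukey``: Tukey-Kramer studentized-range test
    using the one-way mean-square error across all groups.  The returned
    table has one row per pair; adjusted p is never below the raw p.
    """
    if method not in ("sidak", "tukey"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    df = data[[value, group]].dropna()
    groups = {g: sub[value].to_numpy(float) for g, sub in df.groupby(group, observed=True)}
    if len(groups) < 2:
        raise ValueError("post-hoc comparison needs >= 2 groups")
    names = sorted(groups)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    rows = []
    if method == "sidak":
        for a, b in pairs:
            t, dof, p_raw = _pooled_t(groups[a], groups[b])
            p_adj = 1.0 - (1.0 - p_raw) ** m
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": groups[a].mean() - groups[b].mean(),
                    "statistic": t,
                    "df": dof,
                    "p_raw": p_raw,
                    "p_adj": max(p_adj, p_raw),
                }
            )
        note = SIDAK_NOTE
    else:
        k = len(names)
        n_total = sum(len(v) for v in groups.values())
        df_err = n_total - k
        if df_err < 1:
            raise ValueError("not enough observations for Tukey post-hoc")
        mse = (
            sum((len(v) - 1) * v.var(ddof=1) for v in groups.values()) / df_err
        )
        if mse == 0:
            raise ValueError("zero within-group variance: Tukey q undefined")
        for a, b in pairs:
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            diff = groups[a].mean() - groups[b].mean()
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_err))
            t = diff / np.sqrt(mse * (1.0 / na + 1.0 / nb))
            p_raw = 2 * float(sps.t.sf(abs(t), df_err))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": diff,
                    "statistic": q,
                    "df": df_err,
                    "p_raw": p_raw,
                    "p_adj": max(min(p_adj, 1.0), p_raw),
                }
            )
        note = None
    table = pd.DataFrame(rows)
    best = table.loc[table["p_adj"].idxmin()]
    return StatResult(
        test_name=f"posthoc_{method}",
        statistic=float(best["statistic"]),
        df=(float(best["df"]),),
        p_value=float(best["p_adj"]),
        table=table,
        note=note,
    )


def chi_squared(contingency) -> StatResult:
    """Pearson's chi-squared test of independence on an r×c count table."""
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("contingency must be a 2-D table of non-negative counts")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise ValueError("zero row or column total in contingency table")
    expected = np.outer(row_tot, col_tot) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, dof))
    return StatResult(test_name="chi_squared", statistic=stat, df=(dof,), p_value=p)


def two_sample_t(x, y, equal_var: bool = True) -> StatResult:
    """Two-sample t-test, pooled-variance by default (Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return StatResult(
                test_name="two_sample_t",
                statistic=0.0,
                df=(float(len(x) + len(y) - 2),),
                p_value=1.0,
                direction="none",
            )
        raise ValueError("zero variance in both samples with unequal means")
    if equal_var:
        t, dof, p = _pooled_t(x, y)
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        dof = float(res.df)
    direction = "x>y" if t > 0 else ("x<y" if t < 0 else "none")
    return StatResult(
        test_name="two_sample_t", statistic=t, df=(dof,), p_value=p, direction=direction
    )


def pearson_correlation(x, y) -> StatResult:
    """Pearson's r with the two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlation needs >= 3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return StatResult(
        test_name="pearson_correlation",
        statistic=float(r),
        df=(float(len(x) - 2),),
        p_value=float(p),
        direction="positive" if r > 0 else "negative",
    )


def shapiro_wilk(x) -> StatResult:
    """Shapiro-Wilk normality test."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs >= 3 observations")
    w, p = sps.shapiro(x)
    return StatResult(
        test_name="shapiro_wilk", statistic=float(w), df=(float(len(x)),), p_value=float(p)
    )
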