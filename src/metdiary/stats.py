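"""Cohort-level inference: ANOVA, ANCOVA, Tukey HSD, chi-square, and
standardized-coefficient multiple regression.

These wrap scipy/statsmodels with the conventions used for diary-cohort
reporting: covariate-adjusted (least-squares) group means evaluated at the
observed covariate distribution, Tukey–Kramer for unequal group sizes,
listwise deletion of rows with missing covariates, and two-sided tests at
α = .05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class StatsError(ValueError):
    pass


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict = field(default_factory=dict)
    group_ns: dict = field(default_factory=dict)


@dataclass
class AncovaResult:
    adjusted_means: dict
    f_stat: float
    df1: int
    df2: int
    p_value: float
    covariates: list[str] = field(default_factory=list)
    term: str = ""
    n_used: int = 0
    n_dropped: int = 0


@dataclass
class TukeyResult:
    pairwise: dict  # (groupA, groupB) -> (mean difference B-A, adjusted p)


@dataclass
class RegressionResult:
    standardized_betas: dict
    r_squared: float
    see: float
    n: int
    p_value: float
    pvalues: dict = field(default_factory=dict)


def one_way_anova(table: pd.DataFrame, outcome: str, group: str) -> AnovaResult:
    """Classic one-way between/within decomposition."""
    groups = {g: sub[outcome].to_numpy(dtype=float) for g, sub in table.groupby(group, observed=True)}
    if len(groups) < 2:
        raise StatsError("one-way ANOVA needs at least 2 groups")
    small = [g for g, x in groups.items() if len(x) < 2]
    if small:
        raise StatsError(f"groups with <2 observations: {small}")
    f, p = scipy.stats.f_oneway(*groups.values())
    k = len(groups)
    n = sum(len(x) for x in groups.values())
    return AnovaResult(
        f_stat=float(f),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        group_means={g: float(x.mean()) for g, x in groups.items()},
        group_ns={g: len(x) for g, x in groups.items()},
    )


def anova_from_summary(means, sds, ns) -> AnovaResult:
    """One-way ANOVA from per-group means, SDs (n−1) and sizes.

    Algebraically identical to :func:`one_way_anova` on any raw data having
    these summaries; lets printed tables be re-tested without raw data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)):
        raise StatsError("means, sds, ns must have equal length")
    if (ns < 2).any():
        raise StatsError("every group needs n >= 2")
    k, n = len(means), int(ns.sum())
    grand = float((ns * means).sum() / n)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    f = msb / msw
    p = float(scipy.stats.f.sf(f, k - 1, n - k))
    return AnovaResult(
        f_stat=f,
        df_between=k - 1,
        df_within=n - k,
        p_value=p,
        group_means={i: float(m) for i, m in enumerate(means)},
        group_ns={i: int(c) for i, c in enumerate(ns)},
    )


def _covariate_terms(table: pd.DataFrame, covariates: list[str]) -> str:
    parts = []
    for c in covariates:
        if pd.api.types.is_numeric_dtype(table[c]):
            parts.append(c)
        else:
            parts.append(f"C({c})")  # reference level = first observed, by coding order
    return " + ".join(parts)


def _listwise(table: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    sub = table[cols].copy()
    kept = sub.dropna()
    return table.loc[kept.index], len(table) - len(kept)


def _check_collinear(table: pd.DataFrame, covariates: list[str]) -> None:
    for c in covariates:
        if table[c].nunique() < 2:
            raise StatsError(f"degenerate covariate {c!r}: constant column")
    num = [c for c in covariates if pd.api.types.is_numeric_dtype(table[c])]
    if len(num) >= 2:
        x = table[num].to_numpy(dtype=float)
        x = x - x.mean(axis=0)
        rank = np.linalg.matrix_rank(x)
        if rank < len(num):
            corr = np.corrcoef(table[num].to_numpy(dtype=float), rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise StatsError(f"collinear covariates: {num[i]!r} and {num[j]!r}")


def one_way_ancova(
    table: pd.DataFrame, outcome: str, group: str, covariates: list[str]
) -> AncovaResult:
    """Group comparison adjusted for covariates via a linear model.

    Adjusted means are model predictions averaged over the observed
    covariate rows with the group forced to each level in turn
    (the usual least-squares-means convention); the group F is the
    partial (type II) F.
    """
    cols = [outcome, group] + list(covariates)
    data, n_dropped = _listwise(table, cols)
    if covariates:
        _check_collinear(data, list(covariates))
    rhs = f"C({group})"
    if covariates:
        rhs += " + " + _covariate_terms(data, list(covariates))
    model = smf.ols(f"{outcome} ~ {rhs}", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    row = aov.loc[f"C({group})"]
    adj = {}
    for level in sorted(data[group].unique()):
        ghost = data.copy()
        ghost[group] = level
        adj[level] = float(model.predict(ghost).mean())
    return AncovaResult(
        adjusted_means=adj,
        f_stat=float(row["F"]),
        df1=int(row["df"]),
        df2=int(aov.loc["Residual", "df"]),
        p_value=float(row["PR(>F)"]),
        covariates=list(covariates),
        term=group,
        n_used=len(data),
        n_dropped=n_dropped,
    )


def two_way_ancova_interaction(
    table: pd.DataFrame,
    outcome: str,
    factor_a: str,
    factor_b: str,
    covariates: list[str],
) -> AncovaResult:
    """Partial F for the A×B interaction in a two-factor covariate-adjusted
    model. Cell means (adjusted) are returned keyed by (a_level, b_level)."""
    cols = [outcome, factor_a, factor_b] + list(covariates)
    data, n_dropped = _listwise(table, cols)
    cells = data.groupby([factor_a, factor_b], observed=True).size()
    expected = data[factor_a].nunique() * data[factor_b].nunique()
    if len(cells) < expected:
        raise StatsError(f"empty {factor_a}×{factor_b} cell(s); {len(cells)}/{expected} populated")
    rhs = f"C({factor_a}) * C({factor_b})"
    if covariates:
        rhs += " + " + _covariate_terms(data, list(covariates))
    model = smf.ols(f"{outcome} ~ {rhs}", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    row = aov.loc[f"C({factor_a}):C({factor_b})"]
    adj = {}
    for a in sorted(data[factor_a].unique()):
        for b in sorted(data[factor_b].unique()):
            ghost = data.copy()
            ghost[factor_a] = a
            ghost[factor_b] = b
            adj[(a, b)] = float(model.predict(ghost).mean())
    return AncovaResult(
        adjusted_means=adj,
        f_stat=float(row["F"]),
        df1=int(row["df"]),
        df2=int(aov.loc["Residual", "df"]),
        p_value=float(row["PR(>F)"]),
        covariates=list(covariates),
        term=f"{factor_a}:{factor_b}",
        n_used=len(data),
        n_dropped=n_dropped,
    )


def tukey_hsd(table: pd.DataFrame, outcome: str, group: str) -> TukeyResult:
    """All-pairs comparison via the studentized range (Tukey–Kramer for
    unequal n), two-sided, family-wise α = .05."""
    if table[group].nunique() < 2:
        raise StatsError("Tukey HSD needs at least 2 groups")
    res = pairwise_tukeyhsd(
        endog=table[outcome].to_numpy(dtype=float),
        groups=table[group].to_numpy(),
        alpha=0.05,
    )
    pairwise = {}
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    for _, r in frame.iterrows():
        pairwise[(r["group1"], r["group2"])] = (float(r["meandiff"]), float(r["p-adj"]))
    return TukeyResult(pairwise=pairwise)


def chi_square_table(counts) -> tuple[float, int, float]:
    """Pearson chi-square on an r×c contingency table, no continuity
    correction; df = (r−1)(c−1)."""
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise StatsError("contingency table has a zero marginal")
    res = scipy.stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def standardized_regression(
    table: pd.DataFrame, outcome: str, predictors: list[str]
) -> RegressionResult:
    """OLS of the outcome on the predictors with standardized coefficients.

    βs are the slopes after z-scoring outcome and predictors (equivalently,
    raw slope × SDx/SDy); R² and the standard error of the estimate (SEE,
    residual SD in outcome units) come from the raw-scale fit.
    """
    if len(table) <= len(predictors) + 1:
        raise StatsError("need n > predictors + 1")
    X = table[predictors].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise StatsError("perfectly collinear predictors")
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    resid_df = len(y) - X.shape[1] - 1
    see = float(np.sqrt(fit.ssr / resid_df))
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    betas = {p: float(fit.params[i + 1] * sx[i] / sy) for i, p in enumerate(predictors)}
    return RegressionResult(
        standardized_betas=betas,
        r_squared=float(fit.rsquared),
        see=see,
        n=len(y),
        p_value=float(fit.f_pvalue),
        pvalues={p: float(fit.pvalues[i + 1]) for i, p in enumerate(predictors)},
    )
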