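"""Association and agreement statistics used throughout the pipeline.

The group comparisons reported by the stratification study are classical:
odds ratios with Woolf intervals and Fisher/chi-square p-values for 2x2
tables, Mann-Whitney U and Spearman rank tests, summary-statistic Student
t-tests, Welch's ANOVA with eta-squared and Games-Howell post-hoc tests,
two-way random-effects intraclass correlation for inter-rater agreement,
Bland-Altman limits of agreement, and Benjamini-Hochberg multiplicity
control.  Each operation returns a :class:`TestReport` so downstream code
and serialized run reports share one shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestReport",
    "two_by_two",
    "mann_whitney",
    "spearman",
    "t_from_summary",
    "welch_anova",
    "icc_agreement",
    "bland_altman",
    "bh_adjust",
    "one_way_anova",
]


@dataclass
class TestReport:
    """A single statistical test result.

    ``df`` is ``None`` when the statistic has no degrees of freedom
    (e.g. Fisher's exact test); ``ci`` is a (low, high) tuple bracketing
    the point estimate in ``effect_size`` when an interval is defined.
    """

    name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    effect_name: str | None = None
    effect_size: float | None = None
    ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "effect_name": self.effect_name,
            "effect_size": self.effect_size,
            "ci": list(self.ci) if self.ci is not None else None,
        }
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def two_by_two(a: int, b: int, c: int, d: int, *, haldane: bool = True) -> TestReport:
    """Odds ratio and association tests for a 2x2 table.

    Rows are the comparison groups, columns the outcome levels::

                outcome+   outcome-
        group1     a          b
        group2     c          d

    OR = (a*d)/(b*c) with Woolf 95% CI
    ``exp(ln OR +- 1.96*sqrt(1/a+1/b+1/c+1/d))``.  The two-sided Fisher
    p-value follows the minimum-likelihood convention (scipy/R), and the
    chi-square p-value is computed without continuity correction.  A zero
    cell yields OR of ``inf`` or 0 and, when ``haldane``, a CI from the
    table with 0.5 added to every cell, flagged in ``extra``.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("2x2 table requires non-negative integer counts")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("2x2 table has a zero margin; odds ratio undefined")

    zero_cell = (table == 0).any()
    with np.errstate(divide="ignore"):
        if b * c == 0 and a * d > 0:
            odds = math.inf
        elif a * d == 0:
            odds = 0.0
        else:
            odds = (a * d) / (b * c)

    if zero_cell and haldane:
        ah, bh, ch, dh = (x + 0.5 for x in (a, b, c, d))
    else:
        ah, bh, ch, dh = float(a), float(b), float(c), float(d)
    se = math.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    log_or = math.log((ah * dh) / (bh * ch))
    ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))

    fisher_p = sps.fisher_exact(table, alternative="two-sided")[1]
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (exp > 0).all():
        chi2_stat, chi2_p, _, _ = sps.chi2_contingency(table, correction=False)
    else:  # pragma: no cover - excluded by the margin check above
        chi2_stat, chi2_p = math.nan, math.nan

    return TestReport(
        name="two_by_two",
        statistic=chi2_stat,
        p_value=fisher_p,
        df=1,
        effect_name="odds_ratio",
        effect_size=odds,
        ci=ci,
        extra={
            "fisher_p": fisher_p,
            "chi2_p": chi2_p,
            "min_expected": float(exp.min()),
            "haldane_ci": bool(zero_cell and haldane),
        },
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestReport:
    """Two-sided Mann-Whitney U test; U is reported for the first group.

    Uses the exact distribution when feasible (small samples, no ties)
    and a tie-corrected normal approximation otherwise.  Fully tied data
    yields p = 1 with a warning rather than an undefined statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; U test degenerate, p=1")
        return TestReport("mann_whitney_u", statistic=x.size * y.size / 2.0, p_value=1.0)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestReport("mann_whitney_u", statistic=float(res.statistic), p_value=float(res.pvalue))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestReport:
    """Spearman rank correlation with t-approximation p and df = n - 2.

    The effect is reported in the "rho(df)" style used for correlation
    write-ups; ``extra['label']`` carries the formatted string.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires >=3 paired observations")
    rho, p = sps.spearmanr(x, y)
    df = x.size - 2
    return TestReport(
        "spearman_rho",
        statistic=float(rho),
        p_value=float(p),
        df=df,
        effect_name="rho",
        effect_size=float(rho),
        extra={"label": f"rho({df}) = {rho:.2f}"},
    )


# ---------------------------------------------------------------------------
# t-test from summary statistics
# ---------------------------------------------------------------------------

def t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> TestReport:
    """Pooled-variance two-sample Student t-test from printed summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestReport("student_t", statistic=float(t), p_value=float(p), df=n1 + n2 - 2)


# ---------------------------------------------------------------------------
# Welch ANOVA + eta squared + Games-Howell
# ---------------------------------------------------------------------------

def _as_group_frame(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        rows.append(pd.DataFrame({"group": name, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def eta_squared(groups: Mapping[str, Sequence[float]]) -> float:
    """eta^2 = SS_between / SS_total from the classical one-way decomposition."""
    df = _as_group_frame(groups)
    grand = df["value"].mean()
    ss_total = ((df["value"] - grand) ** 2).sum()
    ss_between = sum(
        len(g) * (g["value"].mean() - grand) ** 2 for _, g in df.groupby("group")
    )
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def welch_anova(groups: Mapping[str, Sequence[float]]) -> TestReport:
    """Welch's heteroscedastic one-way ANOVA with Games-Howell post-hoc.

    eta^2 comes from the classical sums-of-squares decomposition (the
    conventional effect size to report alongside the Welch omnibus).
    Groups with fewer than two observations or zero variance are
    rejected by name.
    """
    if len(groups) < 2:
        raise ValueError("Welch ANOVA requires >= 2 groups")
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if np.var(vals) == 0:
            raise ValueError(f"group {name!r} has zero variance")
    df = _as_group_frame(groups)
    aov = pg.welch_anova(data=df, dv="value", between="group")
    gh = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    posthoc = gh[["A", "B", "diff", "se", "T", "df", "pval"]].rename(
        columns={"T": "t", "pval": "p_value"}
    )
    return TestReport(
        "welch_anova",
        statistic=float(aov.loc[0, "F"]),
        p_value=float(aov.loc[0, "p_unc"]),
        df=(float(aov.loc[0, "ddof1"]), float(aov.loc[0, "ddof2"])),
        effect_name="eta_squared",
        effect_size=eta_squared(groups),
        extra={"games_howell": posthoc},
    )


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> TestReport:
    """Classical (equal-variance) one-way ANOVA on per-group observations."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ss_between == 0.0:
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return TestReport(
        "one_way_anova",
        statistic=float(f),
        p_value=float(p),
        df=(k - 1, n - k),
        effect_name="eta_squared",
        effect_size=eta_squared(groups),
    )


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def icc_agreement(ratings: pd.DataFrame) -> TestReport:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a subjects x raters table with no missing cells.
    The F-based 95% CI comes with the estimate.
    """
    if ratings.isna().any().any():
        raise ValueError("missing cells in the ratings table (no imputation)")
    n_subj, n_raters = ratings.shape
    if n_subj < 5 or n_raters < 2:
        raise ValueError("need >=5 subjects and >=2 raters")
    long = ratings.reset_index(names="subject").melt(
        id_vars="subject", var_name="rater", value_name="score"
    )
    res = pg.intraclass_corr(data=long, targets="subject", raters="rater", ratings="score")
    row = res.set_index("Type").loc["ICC(A,1)"]
    lo, hi = row["CI95"]
    return TestReport(
        "icc_2_1",
        statistic=float(row["F"]),
        p_value=float(row["pval"]),
        df=(float(row["df1"]), float(row["df2"])),
        effect_name="icc",
        effect_size=float(row["ICC"]),
        ci=(float(lo), float(hi)),
    )


def bland_altman(pairs: pd.DataFrame | np.ndarray) -> dict:
    """Bland-Altman agreement: bias and 95% limits (bias +- 1.96 * SD of diffs).

    Returns the bias, the limits, and a per-pair (mean, difference) table
    ready for plotting.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) pairs")
    diff = arr[:, 0] - arr[:, 1]
    mean = arr.mean(axis=1)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "table": pd.DataFrame({"mean": mean, "difference": diff}),
    }


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
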