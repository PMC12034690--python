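"""Group-level statistics used across the LDS-test analyses.

Two-sample proportions z-test (pooled, two-sided, no continuity correction),
one-way ANOVA with Scheffé post-hoc, two-way ANOVA (Type II sums of squares
for unbalanced cohorts), one-sample t-tests, Pearson correlation, and the
p-from-z utility that converts printed z statistics to two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "two_prop_z",
    "p_from_z",
    "one_way_anova",
    "scheffe_posthoc",
    "two_way_anova",
    "one_sample_t",
    "pearson_r_test",
]


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    df: tuple | None = None
    group_sizes: tuple = ()
    note: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return self.note is not None and "degenerate" in self.note


def p_from_z(z: float) -> float:
    """Two-sided p from a standard-normal statistic: p = 2*Q(|z|)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(abs(z)))


def two_prop_z(x1: int, n1: int, x2: int, n2: int) -> GroupComparison:
    """Two-sample proportions test with the pooled standard error.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    the p-value is two-sided and no continuity correction is applied. A pooled
    proportion of exactly 0 or 1 leaves z undefined (flagged).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("group totals must be >= 1")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return GroupComparison("two_prop_z", float("nan"), float("nan"),
                               group_sizes=(n1, n2),
                               note="degenerate: pooled proportion is 0 or 1")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return GroupComparison("two_prop_z", float(z), p_from_z(z), group_sizes=(n1, n2))


def one_way_anova(*groups) -> GroupComparison:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    sizes = tuple(g.size for g in groups)
    k, n_total = len(groups), sum(sizes)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if ssw == 0.0:
        return GroupComparison("one_way_anova", float("nan"), float("nan"),
                               df=(k - 1, n_total - k), group_sizes=sizes,
                               note="degenerate: zero within-group variance")
    f, p = sps.f_oneway(*groups)
    return GroupComparison("one_way_anova", float(f), float(p),
                           df=(k - 1, n_total - k), group_sizes=sizes,
                           extras={"ms_within": ssw / (n_total - k)})


def scheffe_posthoc(groups, anova: GroupComparison | None = None,
                    labels=None) -> pd.DataFrame:
    """Scheffé post-hoc contrasts for all group pairs after a one-way ANOVA.

    For pair (i, j): F_pair = (mean_i - mean_j)^2 / (MS_within (1/n_i + 1/n_j));
    p = upper tail of F_{k-1, N-k} at F_pair / (k-1). The (k-1) scaling makes
    Scheffé conservative relative to the unadjusted pairwise contrast.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if anova is None:
        anova = one_way_anova(*groups)
    if anova.degenerate:
        raise ValueError("ANOVA degenerate: zero within-group variance")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    ms_within = anova.extras.get("ms_within")
    if ms_within is None:
        ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
        ms_within = ssw / (n_total - k)
    if labels is None:
        labels = list(range(k))
    df1, df2 = k - 1, n_total - k
    rows = []
    for i, j in combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        diff = gi.mean() - gj.mean()
        f_pair = diff ** 2 / (ms_within * (1 / gi.size + 1 / gj.size))
        p = float(sps.f.sf(f_pair / df1, df1, df2))
        rows.append((labels[i], labels[j], float(diff), float(f_pair), p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff",
                                       "F_pair", "p_value"])


def two_way_anova(values, factor_a, factor_b, ss_type: int = 2) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction.

    Type II sums of squares by default (appropriate for the unbalanced cohort
    sizes these analyses see); reduces to Type I on balanced designs. Returns a
    frame indexed by effect with sum_sq, df, F, p. When a factor-level cell is
    empty the interaction is not estimable: an additive model is fitted and the
    interaction row is flagged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "a": pd.Categorical(factor_a),
        "b": pd.Categorical(factor_b),
    })
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    if np.ptp(df["value"].to_numpy()) == 0.0:
        # constant response: every effect explains nothing
        idx = ["factor_a", "factor_b", "interaction", "residual"]
        out = pd.DataFrame({"sum_sq": 0.0, "df": np.nan, "F": 0.0, "p_value": 1.0},
                           index=idx)
        out.loc["residual", ["F", "p_value"]] = np.nan
        out.attrs["note"] = "degenerate: constant response"
        return out
    cells = df.groupby(["a", "b"], observed=False).size()
    interaction_ok = (cells > 0).all()
    formula = "value ~ C(a) * C(b)" if interaction_ok else "value ~ C(a) + C(b)"
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=ss_type)
    table = table.rename(index={
        "C(a)": "factor_a", "C(b)": "factor_b",
        "C(a):C(b)": "interaction", "Residual": "residual",
    })
    table = table.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p_value"})
    if not interaction_ok:
        table.loc["interaction"] = [np.nan] * table.shape[1]
        table.attrs["note"] = "interaction not estimable: empty cell"
    return table


def one_sample_t(values, mu: float, tail: str = "two") -> GroupComparison:
    """One-sample t-test of mean(values) against the constant ``mu``.

    ``tail``: "lower" (mean < mu), "upper" (mean > mu) or "two". Zero sample
    variance is degenerate: t is undefined; the comparison is decided by the
    sign of (mean - mu) with p reported as 0 (flagged) or 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if tail not in ("lower", "upper", "two"):
        raise ValueError(f"unknown tail {tail!r}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        diff = x.mean() - mu
        if diff == 0:
            return GroupComparison("one_sample_t", float("nan"), 1.0,
                                   df=(x.size - 1,), group_sizes=(x.size,),
                                   note="degenerate: zero variance, mean equals mu")
        effect = ((tail == "lower" and diff < 0) or (tail == "upper" and diff > 0)
                  or tail == "two")
        return GroupComparison("one_sample_t",
                               float(np.sign(diff) * np.inf),
                               0.0 if effect else 1.0,
                               df=(x.size - 1,), group_sizes=(x.size,),
                               note="degenerate: zero variance")
    alternative = {"lower": "less", "upper": "greater", "two": "two-sided"}[tail]
    res = sps.ttest_1samp(x, popmean=mu, alternative=alternative)
    return GroupComparison("one_sample_t", float(res.statistic), float(res.pvalue),
                           df=(x.size - 1,), group_sizes=(x.size,))


def pearson_r_test(x, y) -> GroupComparison:
    """Pearson correlation with its t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = sps.pearsonr(x, y)
    return GroupComparison("pearson_r", float(r), float(p),
                           df=(x.size - 2,), group_sizes=(x.size,))
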