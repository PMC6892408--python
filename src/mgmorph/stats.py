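"""Group statistics for animal-level morphometry tables.

The unit of analysis is one animal x region row.  Each morphometric is
analysed by a two-way ANOVA with interaction (typically genotype x age),
followed by Tukey's HSD over all group pairs, with the conventional
star thresholds (strict inequalities): * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001.

Sums of squares use Type III with sum-to-zero contrasts, which matches
the behaviour of the commercial ANOVA software family commonly used for
this kind of figure and coincides with the classical decomposition on
balanced designs.  Genders are pooled by default; a gender-stratified
analysis is obtained by combining genotype and gender into a single
4-level factor via :func:`combine_factors`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class AnovaEffect:
    """One tested effect: degrees of freedom, SS, F and p."""

    name: str
    df: int
    sum_sq: float
    f: float
    p: float


@dataclass
class AnovaResult:
    """Full-factorial two-way ANOVA table with interaction."""

    factor_a: AnovaEffect
    factor_b: AnovaEffect
    interaction: AnovaEffect
    residual_df: int
    residual_ss: float
    design: dict = field(default_factory=dict)

    @property
    def effects(self) -> dict[str, AnovaEffect]:
        return {
            self.factor_a.name: self.factor_a,
            self.factor_b.name: self.factor_b,
            f"{self.factor_a.name}:{self.factor_b.name}": self.interaction,
        }


def two_way_anova(
    table: pd.DataFrame, factor_a: str, factor_b: str, response: str
) -> AnovaResult:
    """Fit ``response ~ A * B`` and return Type-III F tests per effect.

    Requires at least two levels per factor, no empty design cell, and at
    least one residual degree of freedom.  Rows with a missing response are
    dropped listwise.  If the residual variance is zero the F statistics
    and p-values are reported as NaN with a warning.
    """
    data = table[[factor_a, factor_b, response]].rename(
        columns={factor_a: "A", factor_b: "B", response: "y"}
    )
    if data[["A", "B"]].isna().any().any():
        raise ValueError("factor levels must be non-missing")
    data = data.dropna(subset=["y"])
    levels_a = data["A"].nunique()
    levels_b = data["B"].nunique()
    if levels_a < 2 or levels_b < 2:
        raise ValueError("each factor needs at least two observed levels")
    cell_sizes = data.groupby(["A", "B"], observed=True).size()
    if len(cell_sizes) < levels_a * levels_b:
        raise ValueError("empty design cell: Type-III sums of squares undefined")
    n = len(data)
    residual_df = n - levels_a * levels_b
    if residual_df < 1:
        raise ValueError("no residual degrees of freedom")

    model = ols("y ~ C(A, Sum) * C(B, Sum)", data=data).fit()
    zero_resid = model.ssr <= max(1e-12 * model.centered_tss, 1e-300)
    with warnings.catch_warnings():
        if zero_resid:
            warnings.simplefilter("ignore")  # statsmodels divides by zero MSE
        table3 = anova_lm(model, typ=3)

    def effect(row_name: str, display: str) -> AnovaEffect:
        row = table3.loc[row_name]
        f_stat, p = float(row["F"]), float(row["PR(>F)"])
        if zero_resid:
            f_stat, p = float("nan"), float("nan")
        return AnovaEffect(
            name=display,
            df=int(row["df"]),
            sum_sq=float(row["sum_sq"]),
            f=f_stat,
            p=p,
        )

    if zero_resid:
        warnings.warn(
            "zero residual variance: F and p are undefined", stacklevel=2
        )
    result = AnovaResult(
        factor_a=effect("C(A, Sum)", factor_a),
        factor_b=effect("C(B, Sum)", factor_b),
        interaction=effect("C(A, Sum):C(B, Sum)", f"{factor_a}:{factor_b}"),
        residual_df=int(table3.loc["Residual", "df"]),
        residual_ss=float(table3.loc["Residual", "sum_sq"]),
        design={
            "n": n,
            "levels": {factor_a: levels_a, factor_b: levels_b},
            "cell_sizes": cell_sizes.to_dict(),
        },
    )
    total_df = (
        result.factor_a.df + result.factor_b.df + result.interaction.df
        + result.residual_df
    )
    assert total_df == n - 1, "ANOVA degrees-of-freedom bookkeeping violated"
    return result


def tukey_hsd(table: pd.DataFrame, group_factor: str, response: str) -> pd.DataFrame:
    """All-pairs Tukey HSD using the pooled within-group variance.

    Returns one row per unordered group pair with columns ``group_i,
    group_j, mean_diff, p_adj, significant``.  Requires >= 2 groups with
    >= 2 observations each; a zero pooled variance yields NaN adjusted
    p-values with a warning.
    """
    data = table[[group_factor, response]].dropna()
    counts = data.groupby(group_factor, observed=True).size()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two observations")
    pooled_var = data.groupby(group_factor, observed=True)[response].var().mean()
    if pooled_var == 0:
        warnings.warn(
            "zero pooled within-group variance: adjusted p undefined", stacklevel=2
        )
        from itertools import combinations

        groups = sorted(data[group_factor].unique())
        means = data.groupby(group_factor, observed=True)[response].mean()
        rows = [
            (a, b, float(means[b] - means[a]), float("nan"), False)
            for a, b in combinations(groups, 2)
        ]
        return pd.DataFrame(
            rows, columns=["group_i", "group_j", "mean_diff", "p_adj", "significant"]
        )
    res = pairwise_tukeyhsd(
        endog=data[response].to_numpy(dtype=float),
        groups=data[group_factor].to_numpy(),
    )
    from itertools import combinations

    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group_i": [a for a, _ in pairs],
            "group_j": [b for _, b in pairs],
            "mean_diff": res.meandiffs,
            "p_adj": res.pvalues,
            "significant": res.reject,
        }
    )


def significance_stars(p: float) -> str:
    """Map a p-value to the figure-legend star convention (strict bins)."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "ns"
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def combine_factors(
    table: pd.DataFrame, factors: list[str], name: str = "group", sep: str = "/"
) -> pd.DataFrame:
    """Add a column fusing several factors into one (e.g. genotype x gender).

    Used for the gender-stratified analysis where genotype and gender form
    a single 4-level factor crossed with age.
    """
    out = table.copy()
    out[name] = table[factors].astype(str).agg(sep.join, axis=1)
    return out
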