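"""Cohort statistics: Tukey simultaneous pairwise comparisons and
age x condition interaction regressions.

Tukey's method builds simultaneous 95% confidence intervals for all pairwise
differences between factor-level means from the studentized-range
distribution at the one-way ANOVA residual degrees of freedom, controlling
the family-wise error rate. A pair is significant iff its interval excludes
zero. For k = 2 groups the Tukey interval coincides with the pooled
two-sample t interval (q = sqrt(2) * t).

The interaction regression fits ordinary least squares

    thickness ~ age + condition + age : condition

with a two-level condition (sex or laterality). The interaction coefficient
is the difference between the condition-specific age slopes; its two-tailed
p-value below alpha declares the age trend "inconsistent" between the
condition levels. All tests are two-tailed at alpha = 0.05 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .volume import InputError


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: float) -> float:
    """Studentized-range critical value, cached (ppf is expensive)."""
    return float(sps.studentized_range.ppf(1 - alpha, k, df))


@dataclass
class ComparisonResult:
    """One Tukey pairwise comparison with a simultaneous 95% CI."""

    group_a: object
    group_b: object
    diff_of_means: float  # mean(a) - mean(b), mm
    se: float  # standard error of the difference, mm
    ci_low: float
    ci_high: float
    significant: bool  # CI excludes zero

    def __post_init__(self):
        assert self.ci_low <= self.diff_of_means <= self.ci_high
        assert self.significant == (not self.ci_low <= 0.0 <= self.ci_high)


def tukey_pairwise(
    table: pd.DataFrame,
    grouping: str,
    response: str,
    alpha: float = 0.05,
    welch: bool = False,
) -> list[ComparisonResult]:
    """All k(k-1)/2 pairwise differences with simultaneous (1-alpha) CIs.

    Classic pooled-variance Tukey by default; ``welch=True`` switches to
    unequal-variance (Games–Howell style) per-pair SEs and Welch degrees of
    freedom. Differences are reported as mean(a) - mean(b) with (a, b)
    iterating over sorted level pairs.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    groups = {lvl: np.asarray(sub[response], dtype=float)
              for lvl, sub in table.groupby(grouping, observed=True)}
    if len(groups) < 2:
        raise InputError("need at least two groups for pairwise comparison")
    small = [lvl for lvl, v in groups.items() if len(v) < 2]
    if small:
        raise InputError(f"groups with fewer than 2 observations: {small}")

    levels = sorted(groups)
    n = {lvl: len(groups[lvl]) for lvl in levels}
    mean = {lvl: float(groups[lvl].mean()) for lvl in levels}
    var = {lvl: float(groups[lvl].var(ddof=1)) for lvl in levels}
    n_tot = sum(n.values())
    k = len(levels)
    df_resid = n_tot - k
    mse = sum((n[lvl] - 1) * var[lvl] for lvl in levels) / df_resid
    if mse <= 0:
        raise InputError("zero residual variance; comparisons are degenerate")

    q_pooled = None
    if not welch:  # one quantile serves every pair in the classic method
        q_pooled = _q_crit(alpha, k, float(df_resid))
    results = []
    for a, b in combinations(levels, 2):
        diff = mean[a] - mean[b]
        if welch:
            va, vb = var[a] / n[a], var[b] / n[b]
            se = np.sqrt(va + vb)
            dof = (va + vb) ** 2 / (
                va**2 / (n[a] - 1) + vb**2 / (n[b] - 1)
            )
            q = _q_crit(alpha, k, float(dof))
        else:
            se = np.sqrt(mse * (1.0 / n[a] + 1.0 / n[b]))
            q = q_pooled
        hw = q / np.sqrt(2.0) * se
        lo, hi = diff - hw, diff + hw
        results.append(
            ComparisonResult(a, b, diff, float(se), float(lo), float(hi),
                             not lo <= 0.0 <= hi)
        )
    return results


def get_comparison(
    results: list[ComparisonResult], group_a, group_b
) -> ComparisonResult:
    """Fetch the (a, b) comparison, flipping sign if stored as (b, a)."""
    for r in results:
        if (r.group_a, r.group_b) == (group_a, group_b):
            return r
        if (r.group_a, r.group_b) == (group_b, group_a):
            return ComparisonResult(
                group_a, group_b, -r.diff_of_means, r.se,
                -r.ci_high, -r.ci_low, r.significant,
            )
    raise InputError(f"no comparison between {group_a!r} and {group_b!r}")


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_a": [r.group_a for r in results],
            "group_b": [r.group_b for r in results],
            "diff_of_means": [r.diff_of_means for r in results],
            "se": [r.se for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "significant": [r.significant for r in results],
        }
    )


@dataclass
class RegressionResult:
    """OLS fit of thickness on age, condition and their interaction."""

    response: str
    condition: str
    levels: tuple  # (reference, other); indicator = I(level == other)
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    alpha: float
    sm_result: object = field(repr=False)

    @property
    def interaction_term(self) -> str:
        return f"age:C({self.condition})[T.{self.levels[1]}]"

    @property
    def interaction_coef(self) -> float:
        return float(self.params[self.interaction_term])

    @property
    def interaction_p(self) -> float:
        return float(self.pvalues[self.interaction_term])

    @property
    def age_coef(self) -> float:
        return float(self.params["age"])

    @property
    def consistent(self) -> bool:
        """Age trend consistent between conditions (interaction not significant)."""
        return self.interaction_p >= self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "se": self.bse,
                "p": self.pvalues,
                "ci_low": self.conf_int[0],
                "ci_high": self.conf_int[1],
            }
        )


def fit_interaction_model(
    table: pd.DataFrame, response: str, condition: str, alpha: float = 0.05
) -> RegressionResult:
    """OLS of ``response ~ age * condition`` with two-tailed p-values.

    The interaction coefficient equals slope(other level) - slope(reference
    level), where the reference level is the alphabetically first.
    """
    levels = sorted(table[condition].dropna().unique())
    if len(levels) != 2:
        raise InputError(
            f"condition {condition!r} must have exactly 2 levels, got {levels}"
        )
    if table["age"].nunique() < 4:
        raise InputError("need at least 4 distinct ages to fit the age trend")
    fit = smf.ols(f"{response} ~ age * C({condition})", data=table).fit()
    if fit.df_resid <= 0 or np.linalg.matrix_rank(fit.model.exog) < 4:
        raise InputError("rank-deficient design; cannot fit interaction model")
    ci = fit.conf_int(alpha=alpha)
    return RegressionResult(
        response=response,
        condition=condition,
        levels=(levels[0], levels[1]),
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        conf_int=ci,
        alpha=alpha,
        sm_result=fit,
    )


def ci_band(
    result: RegressionResult, age_grid, alpha: float = 0.05
) -> pd.DataFrame:
    """Pointwise (1-alpha) CI of the conditional mean over an age grid,
    one row per (condition level, age). Warns on extrapolation beyond the
    fitted age range."""
    ages = np.asarray(age_grid, dtype=float)
    fitted_ages = result.sm_result.model.data.frame["age"]
    if ages.min() < fitted_ages.min() or ages.max() > fitted_ages.max():
        warnings.warn("age grid extends beyond the fitted ages (extrapolation)",
                      stacklevel=2)
    frames = []
    for level in result.levels:
        new = pd.DataFrame({"age": ages, result.condition: level})
        pred = result.sm_result.get_prediction(new)
        sf = pred.summary_frame(alpha=alpha)
        frames.append(
            pd.DataFrame(
                {
                    "age": ages,
                    result.condition: level,
                    "mean": sf["mean"].to_numpy(),
                    "ci_low": sf["mean_ci_lower"].to_numpy(),
                    "ci_high": sf["mean_ci_upper"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_group_means(
    table: pd.DataFrame, regions, grouping: str | None = None
) -> pd.DataFrame:
    """Mean and sample SD per region, overall or per group level.

    With a two-level grouping the result also carries a difference column
    (first level minus second in the conventional M-F / R-L orientation:
    for sex the difference is male - female, for side right - left,
    otherwise level0 - level1)."""
    if table.empty:
        raise InputError("empty cohort table")
    regions = list(regions)
    if grouping is None:
        return pd.DataFrame(
            {
                "mean": table[regions].mean(),
                "sd": table[regions].std(ddof=1),
                "n": len(table),
            }
        )
    out = {}
    for level, sub in table.groupby(grouping, observed=True):
        out[f"mean_{level}"] = sub[regions].mean()
        out[f"sd_{level}"] = sub[regions].std(ddof=1) if len(sub) > 1 else np.nan
        out[f"n_{level}"] = len(sub)
    res = pd.DataFrame(out)
    levels = sorted(table[grouping].dropna().unique())
    if len(levels) == 2:
        order = {"sex": ("M", "F"), "side": ("R", "L")}.get(
            grouping, (levels[0], levels[1])
        )
        if set(order) == set(levels):
            res[f"diff_{order[0]}_minus_{order[1]}"] = (
                res[f"mean_{order[0]}"] - res[f"mean_{order[1]}"]
            )
    return res
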