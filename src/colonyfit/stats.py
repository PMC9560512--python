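"""Significance testing, FDR control, error quantification and power analysis.

Fitness differences are tested against zero with two-sided one-sample
t-tests; p-values are adjusted across strains and conditions (within one
assay) by Benjamini-Hochberg FDR.  The assay's empirical error scale is the
RMSE of a one-way fitness ~ strain ANOVA, which feeds a noncentral-t power
analysis giving the minimum detectable fitness difference at a target power.
Reproducibility between independent experiments is summarized by the Pearson
correlation of per-group mean fitness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestPower

__all__ = [
    "one_sample_test",
    "bh_fdr",
    "rmse_anova",
    "rmse_by_strain",
    "t_test_power",
    "power_min_detectable",
    "compare_experiments",
    "fitness_summary",
    "assay_summary",
]


def one_sample_test(values) -> float:
    """Two-sided one-sample t-test p-value against a mean of zero."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 replicates")
    if np.ptp(values) == 0:
        raise ValueError("zero variance; t-test undefined")
    return float(stats.ttest_1samp(values, popmean=0.0).pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rmse_anova(values, groups, denominator: str = "n") -> float:
    """RMSE of the residuals from a one-way ANOVA of values on group.

    ``denominator='n'`` divides the residual sum of squares by the total
    sample size (root mean squared residual); ``'df'`` divides by the
    residual degrees of freedom (n - k).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    k = len(np.unique(groups))
    if k < 2:
        raise ValueError("need at least 2 strains for the ANOVA error model")
    sizes = pd.Series(values).groupby(pd.Series(groups)).size()
    if (sizes < 2).any():
        raise ValueError("every strain needs at least 2 replicates")
    fitted = pd.Series(values).groupby(pd.Series(groups)).transform("mean")
    rss = float(((values - fitted.to_numpy()) ** 2).sum())
    if denominator == "n":
        return float(np.sqrt(rss / values.size))
    if denominator == "df":
        return float(np.sqrt(rss / (values.size - k)))
    raise ValueError("denominator must be 'n' or 'df'")


def rmse_by_strain(
    table: pd.DataFrame, denominator: str = "n",
    value_col: str = "s", strain_col: str = "strain",
    condition_col: str = "condition",
) -> pd.Series:
    """Per-condition ANOVA RMSE of the fitness ~ strain model."""
    return table.groupby(condition_col, sort=True).apply(
        lambda g: rmse_anova(g[value_col], g[strain_col], denominator=denominator),
        include_groups=False,
    )


def t_test_power(effect: float, n: int, sd: float, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided one-sample t-test for a mean shift."""
    if sd <= 0 or n < 2:
        raise ValueError("sd must be positive and n >= 2")
    return float(TTestPower().power(effect_size=effect / sd, nobs=n,
                                    alpha=alpha, alternative="two-sided"))


def power_min_detectable(
    n: int, sd: float, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Minimum detectable fitness difference at the target power.

    Solves the noncentral-t power equation of the two-sided one-sample
    t-test for the standardized effect with exactly ``power``, and scales it
    by the error SD.  Raises if no finite solution exists in a wide bracket
    (e.g. n = 2 with extreme error).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if n < 2 or sd <= 0:
        raise ValueError("need n >= 2 and sd > 0")
    try:
        d = TTestPower().solve_power(effect_size=None, nobs=n, alpha=alpha,
                                     power=power, alternative="two-sided")
    except Exception as exc:  # pragma: no cover - solver failure path
        raise ValueError(f"no finite effect size reaches power {power}") from exc
    d = float(np.atleast_1d(d)[0])
    if not np.isfinite(d) or d <= 0:
        raise ValueError(f"no finite effect size reaches power {power} at n={n}")
    return d * sd


def compare_experiments(
    set_a: pd.DataFrame, set_b: pd.DataFrame,
    value_col: str = "s", keys: tuple = ("strain", "condition"),
) -> float:
    """Pearson r of per-group mean fitness between two experiments.

    Groups are strain x condition; at least 3 groups must be shared.
    """
    keys = list(keys)
    ma = set_a.groupby(keys)[value_col].mean()
    mb = set_b.groupby(keys)[value_col].mean()
    joined = pd.concat({"a": ma, "b": mb}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} shared strain-condition groups; need >= 3"
        )
    return float(stats.pearsonr(joined["a"], joined["b"]).statistic)


def fitness_summary(
    table: pd.DataFrame, value_col: str = "s",
    keys: tuple = ("strain", "condition"), alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group mean, t-based 95% CI, t-test p and BH q across groups."""
    rows = []
    for key, g in table.groupby(list(keys)):
        vals = g[value_col].to_numpy(dtype=float)
        n = vals.size
        mean = vals.mean()
        if n >= 2 and np.ptp(vals) > 0:
            sem = vals.std(ddof=1) / np.sqrt(n)
            half = stats.t.ppf(0.975, n - 1) * sem
            p = one_sample_test(vals)
        else:
            half, p = np.nan, np.nan
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update({"n": n, "mean_s": mean, "ci_low": mean - half,
                    "ci_high": mean + half, "p": p})
        rows.append(rec)
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def assay_summary(
    table: pd.DataFrame, value_col: str = "s", alpha: float = 0.05,
    power: float = 0.80, denominator: str = "n",
) -> pd.DataFrame:
    """Per-condition measurement properties: RMSE, variance explained by
    strain, and minimum detectable fitness difference at the target power
    (computed at that condition's median replicate count)."""
    from .normalization import variance_explained

    rows = []
    for cond, g in table.groupby("condition"):
        rmse = rmse_anova(g[value_col], g["strain"], denominator=denominator)
        r2 = variance_explained(g[value_col].to_numpy(), g["strain"].to_numpy())
        n_rep = int(g.groupby("strain").size().median())
        mdd = power_min_detectable(n_rep, rmse, alpha=alpha, power=power)
        rows.append({"condition": cond, "rmse": rmse, "r_squared": r2,
                     "n_replicates": n_rep, "min_detectable": mdd})
    return pd.DataFrame(rows)
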