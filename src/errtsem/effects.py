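"""Age-effect regressions and auxiliary univariate statistics.

Age effects are estimated by ordinary least squares with linear and
quadratic terms for mean-centered age; following the emphasis on effect
sizes over p-values at this sample size, the headline quantity is the
model R-squared with a confidence interval obtained by inverting the
noncentral-F distribution of the overall test (a percentile-bootstrap
alternative is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errt import net_scores_frame

__all__ = ["EffectEstimate", "age_glm", "net_score_age_correlations", "paired_t", "r2_confint"]


@dataclass
class EffectEstimate:
    outcome: str
    intercept: float
    beta_age: float
    beta_age2: float
    r2: float
    r2_ci: tuple[float, float]
    f_stat: float
    df_model: int
    df_resid: int
    p: float

    def __post_init__(self) -> None:
        lo, hi = self.r2_ci
        if not (0.0 <= lo <= self.r2 <= hi <= 1.0):
            raise ValueError("R-squared CI must contain the estimate within [0, 1]")


def r2_confint(r2: float, df_model: int, df_resid: int, level: float = 0.95) -> tuple[float, float]:
    """CI for the population R-squared by noncentral-F inversion.

    The observed F statistic is referred to noncentral-F distributions with
    noncentrality lambda; the confidence bounds are the lambdas at which the
    observed F sits at the (1 +/- level)/2 tail, mapped back through
    R^2 = lambda / (lambda + n).
    """
    n = df_model + df_resid + 1
    if r2 >= 1.0:
        return (1.0, 1.0)
    f_obs = (r2 / df_model) / ((1 - r2) / df_resid)
    alpha = 1 - level

    def cdf(lam: float) -> float:  # decreasing in lam
        val = float(stats.ncf.cdf(f_obs, df_model, df_resid, lam))
        # scipy's ncf underflows to NaN at extreme noncentrality, where the
        # true cdf is numerically 0
        return 0.0 if np.isnan(val) else val

    lam_max = 10.0 * (f_obs * df_model + n) + 100.0
    while cdf(lam_max) > alpha / 2 and lam_max < 1e8:
        lam_max *= 10.0

    def invert(target: float) -> float:
        if cdf(0.0) <= target:
            return 0.0
        return float(optimize.brentq(lambda l: cdf(l) - target, 0.0, lam_max))

    lam_hi = invert(alpha / 2)
    lam_lo = invert(1 - alpha / 2)
    lo = lam_lo / (lam_lo + n)
    hi = lam_hi / (lam_hi + n)
    lo, hi = min(lo, r2), max(hi, r2)
    return (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def _r2_ci_bootstrap(
    y: np.ndarray, X: np.ndarray, rng: np.random.Generator, n_boot: int = 999, level: float = 0.95
) -> tuple[float, float]:
    n = len(y)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = sm.OLS(y[idx], X[idx]).fit().rsquared
    alpha = 1 - level
    return tuple(np.quantile(vals, [alpha / 2, 1 - alpha / 2]))


def age_glm(
    y,
    age,
    include_quadratic: bool = True,
    outcome: str = "y",
    ci_method: str = "ncf",
    seed: int = 0,
) -> EffectEstimate:
    """OLS of an outcome on (centered) linear and quadratic age terms.

    Reports the full-model R-squared, its confidence interval (noncentral-F
    inversion by default, ``ci_method="bootstrap"`` for the percentile
    bootstrap), the overall F test and coefficients.  A constant outcome
    yields R-squared 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(y) != len(age):
        raise ValueError("y and age must have equal length")
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    a = age - age.mean()
    cols = [np.ones_like(a), a]
    if include_quadratic:
        cols.append(a**2)
    X = np.column_stack(cols)
    if np.ptp(y) == 0:
        warnings.warn("constant outcome: R-squared defined as 0")
        return EffectEstimate(outcome, float(y[0]), 0.0, 0.0, 0.0, (0.0, 0.0),
                              0.0, X.shape[1] - 1, len(y) - X.shape[1], 1.0)
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared)
    dfm, dfr = int(res.df_model), int(res.df_resid)
    if ci_method == "ncf":
        ci = r2_confint(r2, dfm, dfr)
    elif ci_method == "bootstrap":
        ci = _r2_ci_bootstrap(y, X, np.random.default_rng(seed))
        ci = (min(ci[0], r2), max(ci[1], r2))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return EffectEstimate(
        outcome=outcome,
        intercept=float(res.params[0]),
        beta_age=float(res.params[1]),
        beta_age2=float(res.params[2]) if include_quadratic else 0.0,
        r2=r2,
        r2_ci=ci,
        f_stat=float(res.fvalue),
        df_model=dfm,
        df_resid=dfr,
        p=float(res.f_pvalue),
    )


def net_score_age_correlations(net: pd.DataFrame, age) -> dict[str, tuple[float, float]]:
    """Pearson correlations of the three net scores with age.

    ``net`` may be a net-score table (three ``net_*`` columns) or a raw
    rating table, in which case net scores are computed first.  Returns
    ``{score name: (r, two-sided p)}`` over complete cases.
    """
    orig = net
    if "net_positive_reactivity" not in net.columns:
        net = net_scores_frame(net)
    if len(age) != len(orig):
        raise ValueError("age must align with the input table")
    age = pd.Series(np.asarray(age, dtype=float), index=orig.index).loc[net.index]
    out = {}
    for col in ("net_positive_reactivity", "net_negative_reactivity", "net_negative_regulation"):
        mask = net[col].notna() & age.notna()
        x, y = net.loc[mask, col], age[mask]
        if mask.sum() < 3:
            raise ValueError("need at least 3 complete cases")
        r, p = stats.pearsonr(x, y)
        out[col] = (float(r), float(p))
    return out


def paired_t(a, b) -> tuple[float, float]:
    """Paired t test; raises on zero-variance differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.ptp(a - b) == 0:
        raise ValueError("differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
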