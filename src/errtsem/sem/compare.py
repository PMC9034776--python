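"""Scaled chi-square difference tests for nested covariance-structure models."""

from __future__ import annotations

import warnings

from scipy import stats

from .estimator import FitResult

__all__ = ["scaled_chi2_diff", "format_p"]


def _free_keys(result: FitResult) -> set[tuple[str, str, str]]:
    ram = result._model
    return {ram.table[row].key() for rows in ram.free_members for row in rows}


def _check_nested(restricted: FitResult, full: FitResult, check: str = "strict") -> None:
    if set(restricted._model.obs) != set(full._model.obs):
        raise ValueError("models are not nested: different observed variables")
    if restricted.df < full.df:
        raise ValueError("restricted model must have at least as many df as the full model")
    if check == "df":
        return
    extra = _free_keys(restricted) - _free_keys(full)
    if extra:
        raise ValueError(f"models are not nested: restricted frees {sorted(extra)} not free in full")


def scaled_chi2_diff(
    restricted: FitResult, full: FitResult, check: str = "strict"
) -> tuple[float, int, float]:
    """Mean-scaled difference test between two nested fits.

    Uses the difference-of-scaled-statistics form with pooled scaling
    c_d = (df0 c0 - df1 c1) / (df0 - df1); negative scaled differences (or a
    non-positive pooled scale) are floored at zero with a warning.  Returns
    (delta_chi2, delta_df, p).  Identical models give (0, 0, 1).

    ``check="strict"`` requires the restricted model's free parameters to be
    a subset of the full model's; ``check="df"`` relaxes this to the df
    ordering, for pairs nested through constraints that the parameter tables
    cannot express (e.g. a single general factor versus correlated factors).
    """
    for fit in (restricted, full):
        if fit.converged == "dnc":
            raise RuntimeError("cannot compare a non-converged fit")
    _check_nested(restricted, full, check=check)
    delta_df = restricted.df - full.df
    if delta_df == 0:
        return 0.0, 0, 1.0
    c0 = restricted.sb_scaling if restricted.sb_scaling else 1.0
    c1 = full.sb_scaling if full.sb_scaling else 1.0
    cd = (restricted.df * c0 - full.df * c1) / delta_df
    raw = restricted.chi2_ml - full.chi2_ml
    if cd <= 0:
        warnings.warn("non-positive pooled scaling; difference statistic floored at 0")
        delta = 0.0
    else:
        delta = raw / cd
    if delta < 0:
        warnings.warn("negative scaled chi-square difference floored at 0")
        delta = 0.0
    p = float(stats.chi2.sf(delta, delta_df))
    return float(delta), int(delta_df), p


def format_p(p: float, floor: float = 2.2e-16) -> str:
    """Report p-values below representable precision as '< 2.2e-16'."""
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3g}"
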