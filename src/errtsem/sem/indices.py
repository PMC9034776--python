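"""Fit indices and information criteria for covariance-structure models."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["fit_indices", "aic"]


def fit_indices(
    chi2: float,
    df: int,
    N: int,
    baseline_chi2: float,
    baseline_df: int,
) -> tuple[float, float]:
    """RMSEA and CFI from a test statistic and its independence baseline.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (N-1))); CFI compares the
    noncentrality of the model to that of the baseline, clamped to [0, 1].
    A zero-df (saturated) model has RMSEA defined as 0 with a warning.
    """
    if df < 0 or baseline_df < 0:
        raise ValueError("degrees of freedom must be nonnegative")
    if N <= 1:
        raise ValueError("N must exceed 1")
    if df == 0:
        warnings.warn("df = 0: RMSEA defined as 0 for a saturated model")
        rmsea = 0.0
    else:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (N - 1))))
    num = max(chi2 - df, 0.0)
    den = max(baseline_chi2 - baseline_df, num, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    return rmsea, float(np.clip(cfi, 0.0, 1.0))


def aic(fit) -> float:
    """Akaike information criterion, -2 loglik + 2 * n_free parameters."""
    if fit.converged == "dnc":
        raise RuntimeError("AIC is undefined for a non-converged fit")
    return -2.0 * fit.loglik + 2.0 * fit.n_free
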