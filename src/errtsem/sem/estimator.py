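"""Maximum-likelihood covariance-structure estimation with robust inference.

The model is held in RAM form: with ``v`` the stacked vector of observed
and latent variables, ``A`` collects directed paths (loadings and
regressions), ``S`` symmetric (co)variances, and the model-implied
covariance of the observed block is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T,

where ``F`` selects the observed rows.  The ML discrepancy

    F_ML(theta) = log|Sigma| + tr(S_sample Sigma^-1) - log|S_sample| - p

is minimized by quasi-Newton iteration with analytic gradients; free
variances are optimized on the log scale so they stay positive, and
near-zero estimates are flagged as boundary (Heywood) solutions rather
than truncated silently.

Non-normality-robust inference follows the classic mean-scaling
correction: with ``Delta`` the Jacobian of vech Sigma, ``V`` the
normal-theory weight matrix and ``Gamma`` the empirical fourth-moment
covariance of vech S, the scaling factor is ``c = tr(U Gamma)/df`` for the
residual weight matrix ``U``, the scaled statistic is ``chi2_ml / c``, and
standard errors come from the sandwich ``(D'VD)^-1 D'V Gamma V D (D'VD)^-1 / N``.
Modification indices are univariate score tests for fixed or absent
parameters, with expected parameter changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spec import (
    COVARIANCE,
    LOADING,
    REGRESSION,
    VARIANCE,
    ModelSpec,
    ModelSpecError,
    Parameter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMoments",
    "FitResult",
    "ModIndex",
    "SEM",
    "IdentificationError",
    "fit_ml",
    "satorra_bentler",
    "modification_indices",
    "implied_covariance",
]


class IdentificationError(ValueError):
    """The model has more free parameters than moments or a rank-deficient Jacobian."""


# --------------------------------------------------------------------------
# sample moments
# --------------------------------------------------------------------------


@dataclass
class SampleMoments:
    """Covariance estimate S (divisor N-1), its sample size, and raw data.

    Raw data (complete cases) are needed for the fourth-moment matrix behind
    the robust corrections; moment-only input supports naive ML fits.
    """

    S: np.ndarray
    N: int
    var_names: list[str]
    data: np.ndarray | None = None  # N x p, complete cases, same column order

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = len(self.var_names)
        if self.S.shape != (p, p):
            raise ValueError("S shape does not match var_names")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if self.N <= p:
            raise ValueError(f"need N > p for estimation (N={self.N}, p={p})")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, var_names: Sequence[str] | None = None) -> "SampleMoments":
        if var_names is None:
            var_names = list(df.columns)
        sub = df[list(var_names)].astype(float)
        n_before = len(sub)
        sub = sub.dropna()
        if len(sub) < n_before:
            logger.info("dropped %d incomplete case(s)", n_before - len(sub))
        X = sub.to_numpy()
        S = np.cov(X, rowvar=False, ddof=1)
        return cls(S=S, N=X.shape[0], var_names=list(var_names), data=X)

    def reordered(self, var_names: Sequence[str]) -> "SampleMoments":
        missing = [v for v in var_names if v not in self.var_names]
        if missing:
            raise ValueError(f"variables not in sample moments: {missing}")
        idx = [self.var_names.index(v) for v in var_names]
        return SampleMoments(
            S=self.S[np.ix_(idx, idx)],
            N=self.N,
            var_names=list(var_names),
            data=None if self.data is None else self.data[:, idx],
        )


# --------------------------------------------------------------------------
# vech / duplication helpers
# --------------------------------------------------------------------------


def _vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.tril_indices(p)
    return rows, cols


def _vech(M: np.ndarray) -> np.ndarray:
    r, c = _vech_indices(M.shape[0])
    return M[r, c]


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix D with vec(M) = D vech(M) for symmetric M."""
    r, c = _vech_indices(p)
    nstar = len(r)
    D = np.zeros((p * p, nstar))
    for k, (i, j) in enumerate(zip(r, c)):
        D[i * p + j, k] = 1.0
        if i != j:
            D[j * p + i, k] = 1.0
    return D


# --------------------------------------------------------------------------
# RAM machinery
# --------------------------------------------------------------------------


class _RAMModel:
    """Parameter bookkeeping and Sigma/gradient evaluation for one spec."""

    def __init__(self, spec: ModelSpec, identification: str = "unit_variance"):
        self.spec = spec
        self.identification = identification
        self.table = spec.parameter_table(identification)
        self.obs = spec.observed_vars
        self.lat = list(spec.latent_factors)
        self.names = self.obs + self.lat
        self.p = len(self.obs)
        self.n = len(self.names)
        self._ix = {v: i for i, v in enumerate(self.names)}

        # map each table row to a matrix entry
        self.entries: list[tuple[str, int, int]] = []
        for par in self.table:
            if par.kind in (LOADING, REGRESSION):
                if par.kind == LOADING:
                    i, j = self._ix[par.rhs], self._ix[par.lhs]  # indicator <- factor
                else:
                    i, j = self._ix[par.lhs], self._ix[par.rhs]  # outcome <- predictor
                self.entries.append(("A", i, j))
            else:
                i, j = self._ix[par.lhs], self._ix[par.rhs]
                self.entries.append(("S", min(i, j), max(i, j)))

        # free parameter slots (merged by label)
        self.free_names: list[str] = []
        self.free_is_variance: list[bool] = []
        self.free_members: list[list[int]] = []  # table row indices
        slot_of_label: dict[str, int] = {}
        self.slot_of_row: dict[int, int] = {}
        for row, par in enumerate(self.table):
            if not par.free:
                continue
            if par.label is not None and par.label in slot_of_label:
                k = slot_of_label[par.label]
                self.free_members[k].append(row)
            else:
                k = len(self.free_names)
                self.free_names.append(par.label or par.name)
                self.free_is_variance.append(par.kind == VARIANCE)
                self.free_members.append([row])
                if par.label is not None:
                    slot_of_label[par.label] = k
            self.slot_of_row[row] = k
        self.q = len(self.free_names)
        self.nstar = self.p * (self.p + 1) // 2

    # -- start values ------------------------------------------------------
    def start_values(self, S: np.ndarray) -> np.ndarray:
        sd = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        sd_of = {v: sd[i] for i, v in enumerate(self.obs)}
        endogenous = {p.rhs for p in self.spec.loadings} | {
            p.lhs for p in self.spec.regressions
        }
        theta0 = np.zeros(self.q)
        for k, rows in enumerate(self.free_members):
            par = self.table[rows[0]]
            if par.kind == LOADING:
                if par.rhs in sd_of:
                    val = 0.7 * sd_of[par.rhs]
                else:  # second-order loading onto a latent
                    val = 0.5
            elif par.kind == REGRESSION:
                val = 0.0
            elif par.kind == VARIANCE:
                if par.lhs not in sd_of:
                    val = 1.0
                elif par.lhs in endogenous:
                    val = 0.5 * sd_of[par.lhs] ** 2  # residual variance
                else:  # exogenous observed: the (saturated) sample variance
                    val = sd_of[par.lhs] ** 2
            else:  # covariance
                if par.lhs in sd_of and par.rhs in sd_of:
                    if par.lhs in endogenous or par.rhs in endogenous:
                        val = 0.0  # residual covariance
                    else:  # exogenous pair: start at the sample covariance
                        i, j = self.obs.index(par.lhs), self.obs.index(par.rhs)
                        val = float(S[i, j])
                elif par.lhs not in sd_of and par.rhs not in sd_of:
                    # latent-latent: a modest nonzero start keeps factors
                    # with only two indicators locally identified
                    val = 0.3
                else:
                    val = 0.0
            if par.value is not None and par.free:
                val = par.value  # explicit start hint
            theta0[k] = val
        return theta0

    # -- matrix assembly ---------------------------------------------------
    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = np.zeros((self.n, self.n))
        Smat = np.zeros((self.n, self.n))
        for row, par in enumerate(self.table):
            kind, i, j = self.entries[row]
            val = theta[self.slot_of_row[row]] if par.free else float(par.value)
            if kind == "A":
                A[i, j] = val
            else:
                Smat[i, j] = val
                Smat[j, i] = val
        return A, Smat

    def implied(self, theta: np.ndarray) -> np.ndarray:
        A, Smat = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.n) - A)
        C = B @ Smat @ B.T
        return C[: self.p, : self.p]

    # -- discrepancy + gradient (natural parameter scale) --------------------
    def fml_grad(self, theta: np.ndarray, S: np.ndarray, logdetS: float) -> tuple[float, np.ndarray]:
        A, Smat = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.n) - A)
        C = B @ Smat @ B.T
        Sigma = C[: self.p, : self.p]
        bump = 0.0
        try:
            cho = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            evals = np.linalg.eigvalsh(Sigma)
            bump = abs(float(evals[0])) + 1e-3
            Sigma = Sigma + bump * np.eye(self.p)
            cho = np.linalg.cholesky(Sigma)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho))))
        Sigma_inv = np.linalg.inv(Sigma)
        f = logdet + float(np.sum(Sigma_inv * S)) - logdetS - self.p
        if bump:
            f += 1e3 * bump
        W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
        Wfull = np.zeros((self.n, self.n))
        Wfull[: self.p, : self.p] = W
        gradA = 2.0 * (B.T @ Wfull @ C)
        gradS = B.T @ Wfull @ B
        grad = np.zeros(self.q)
        for row, par in enumerate(self.table):
            if not par.free:
                continue
            kind, i, j = self.entries[row]
            if kind == "A":
                g = gradA[i, j]
            else:
                g = 2.0 * gradS[i, j] if i != j else gradS[i, i]
            grad[self.slot_of_row[row]] += g
        return f, grad

    # -- Jacobian of vech Sigma wrt free parameters (natural scale) ---------
    def delta(self, theta: np.ndarray) -> np.ndarray:
        A, Smat = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.n) - A)
        C = B @ Smat @ B.T
        Bp = B[: self.p, :]
        r, c = _vech_indices(self.p)
        Delta = np.zeros((self.nstar, self.q))
        for row, par in enumerate(self.table):
            if not par.free:
                continue
            kind, i, j = self.entries[row]
            dSig = self._dsigma(kind, i, j, Bp, C)
            Delta[:, self.slot_of_row[row]] += dSig[r, c]
        return Delta

    def _dsigma(self, kind: str, i: int, j: int, Bp: np.ndarray, C: np.ndarray) -> np.ndarray:
        if kind == "A":
            # dSigma = F B E_ij C F' + (...)^T with C = B S B'
            M = np.outer(Bp[:, i], C[j, : self.p])
            return M + M.T
        if i == j:
            return np.outer(Bp[:, i], Bp[:, i])
        M = np.outer(Bp[:, i], Bp[:, j])
        return M + M.T

    def candidate_dsigma_grad(
        self, par: Parameter, theta: np.ndarray, S: np.ndarray
    ) -> tuple[np.ndarray, float]:
        """(vech dSigma/dphi, dF_ML/dphi) for a parameter absent/fixed in the model."""
        A, Smat = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.n) - A)
        C = B @ Smat @ B.T
        Bp = B[: self.p, :]
        Sigma = C[: self.p, : self.p]
        Sigma_inv = np.linalg.inv(Sigma)
        W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
        if par.kind in (LOADING, REGRESSION):
            if par.kind == LOADING:
                i, j = self._ix[par.rhs], self._ix[par.lhs]
            else:
                i, j = self._ix[par.lhs], self._ix[par.rhs]
            kind = "A"
        else:
            i, j = sorted((self._ix[par.lhs], self._ix[par.rhs]))
            kind = "S"
        dSig = self._dsigma(kind, i, j, Bp, C)
        r, c = _vech_indices(self.p)
        g = float(np.sum(W * dSig))
        return dSig[r, c], g


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------


@dataclass
class ModIndex:
    parameter: str
    mi: float
    epc: float


@dataclass
class FitResult:
    """Estimates, robust statistics and fit indices for one fitted model."""

    spec: ModelSpec
    identification: str
    converged: str  # converged | dnc | boundary
    N: int
    p: int
    df: int
    n_free: int
    free_names: list[str]
    chi2_ml: float
    loglik: float
    aic_: float
    sb_scaling: float | None = None
    chi2_sb: float | None = None
    rmsea: float = np.nan
    cfi: float = np.nan
    rmsea_ml: float = np.nan
    cfi_ml: float = np.nan
    baseline_chi2: float = np.nan
    baseline_df: int = 0
    baseline_scaling: float = 1.0
    heywood_flags: list[str] = field(default_factory=list)
    n_iter: int = 0
    grad_norm: float = np.nan
    _theta: np.ndarray | None = None
    _se_robust: np.ndarray | None = None
    _model: "_RAMModel | None" = None
    _moments: SampleMoments | None = None

    def _require_converged(self) -> None:
        if self.converged == "dnc":
            raise RuntimeError("model did not converge; estimates are not available")

    @property
    def theta(self) -> dict[str, float]:
        self._require_converged()
        return dict(zip(self.free_names, np.asarray(self._theta, dtype=float)))

    @property
    def se_robust(self) -> dict[str, float]:
        self._require_converged()
        if self._se_robust is None:
            raise RuntimeError("robust standard errors not computed (raw data required)")
        return dict(zip(self.free_names, np.asarray(self._se_robust, dtype=float)))

    @property
    def implied_cov(self) -> np.ndarray:
        self._require_converged()
        return self._model.implied(self._theta)

    def estimate(self, name: str) -> float:
        return self.theta[name]

    def standardized_loadings(self) -> dict[str, float]:
        """Loadings divided by model-implied indicator standard deviations."""
        self._require_converged()
        Sigma = self.implied_cov
        sd = {v: float(np.sqrt(Sigma[i, i])) for i, v in enumerate(self._model.obs)}
        out = {}
        theta = self.theta
        for par in self._model.table:
            if par.kind == LOADING and par.rhs in sd:
                val = theta.get(par.label or par.name, par.value if not par.free else None)
                if val is None:
                    continue
                out[par.name] = float(val) / sd[par.rhs]
        return out

    def to_dict(self) -> dict:
        d = {
            "converged": self.converged,
            "N": self.N,
            "p": self.p,
            "df": self.df,
            "n_free": self.n_free,
            "chi2_ml": self.chi2_ml,
            "chi2_sb": self.chi2_sb,
            "sb_scaling": self.sb_scaling,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "aic": self.aic_,
            "loglik": self.loglik,
            "heywood_flags": self.heywood_flags,
        }
        if self.converged != "dnc":
            d["estimates"] = self.theta
            if self._se_robust is not None:
                d["se_robust"] = self.se_robust
        return d


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------


class SEM:
    """Covariance-structure (SEM/CFA) maximum-likelihood estimator.

    scikit-learn style: construct with a model (DSL text or
    :class:`ModelSpec`), then ``fit(X)`` with a DataFrame or
    :class:`SampleMoments`; results live in fitted attributes
    (``result_``, ``chi2_sb_``, ``rmsea_`` ...).

    Parameters
    ----------
    model:
        DSL text or parsed :class:`ModelSpec`.
    identification:
        ``"unit_variance"`` (latent variances fixed to 1; the default,
        matching fully standardized reporting) or ``"marker"`` (first
        loading fixed to 1).
    robust:
        Compute the mean-scaled test statistic and sandwich standard
        errors (requires raw data).
    index_variant:
        ``"scaled"`` computes RMSEA/CFI from the scaled statistic (default);
        ``"ml"`` uses the naive ML statistic.
    """

    def __init__(
        self,
        model: str | ModelSpec,
        identification: str = "unit_variance",
        robust: bool = True,
        index_variant: str = "scaled",
        max_iter: int = 1000,
        gtol: float = 1e-6,
    ):
        self.model = model
        self.identification = identification
        self.robust = robust
        self.index_variant = index_variant
        self.max_iter = max_iter
        self.gtol = gtol

    # sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {
            "model": self.model,
            "identification": self.identification,
            "robust": self.robust,
            "index_variant": self.index_variant,
            "max_iter": self.max_iter,
            "gtol": self.gtol,
        }

    def set_params(self, **params) -> "SEM":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame | SampleMoments, y=None) -> "SEM":
        spec = self.model if isinstance(self.model, ModelSpec) else ModelSpec.from_text(self.model)
        ram = _RAMModel(spec, self.identification)
        if isinstance(X, SampleMoments):
            moments = X.reordered(ram.obs)
        else:
            moments = SampleMoments.from_dataframe(X, ram.obs)
        S, N, p = moments.S, moments.N, ram.p

        sign, logdetS = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance matrix is not positive definite")
        if ram.q > ram.nstar:
            raise IdentificationError(
                f"{ram.q} free parameters exceed {ram.nstar} sample moments"
            )

        theta0 = ram.start_values(S)
        if np.linalg.matrix_rank(ram.delta(theta0), tol=1e-8) < ram.q:
            raise IdentificationError("model Jacobian is rank deficient at start values")

        # optimize on an unconstrained scale: log for free variances
        is_var = np.asarray(ram.free_is_variance)
        lo = np.clip(theta0, 1e-4, None)

        def to_internal(th: np.ndarray) -> np.ndarray:
            z = th.copy()
            z[is_var] = np.log(np.clip(th[is_var], 1e-10, None))
            return z

        def to_natural(z: np.ndarray) -> np.ndarray:
            th = z.copy()
            th[is_var] = np.exp(np.clip(z[is_var], -40.0, 40.0))
            return th

        z0 = to_internal(np.where(is_var, lo, theta0))

        def objective(z: np.ndarray) -> tuple[float, np.ndarray]:
            th = to_natural(z)
            try:
                f, g = ram.fml_grad(th, S, logdetS)
            except np.linalg.LinAlgError:
                f, g = np.nan, None
            if not np.isfinite(f) or g is None or not np.all(np.isfinite(g)):
                # infeasible region (non-PD implied covariance or overflow):
                # climb back toward the start values
                d = z - z0
                return 1e8 * (1.0 + float(d @ d)), 2e8 * d
            g = g.copy()
            g[is_var] *= th[is_var]  # chain rule for log-variances
            return f, g
        res = optimize.minimize(
            objective,
            z0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": 1e-13, "maxcor": 40},
        )
        theta = to_natural(res.x)
        try:
            fval, grad = ram.fml_grad(theta, S, logdetS)
            grad_norm = float(np.max(np.abs(grad)))
        except np.linalg.LinAlgError:
            fval, grad_norm = np.inf, np.inf
        converged = (
            "converged" if (np.isfinite(fval) and (res.success or grad_norm < 1e-4)) else "dnc"
        )

        # Heywood / boundary detection on observed residual variances
        heywood: list[str] = []
        scale = float(np.median(np.diag(S)))
        for k, rows in enumerate(ram.free_members):
            par = ram.table[rows[0]]
            if par.kind == VARIANCE and par.lhs in ram.obs and theta[k] < 1e-3 * scale:
                heywood.append(par.lhs)
        if heywood and converged == "converged":
            converged = "boundary"

        chi2_ml = max(float((N - 1) * fval), 0.0)
        df = ram.nstar - ram.q
        S_biased = S * (N - 1) / N
        Sigma = ram.implied(theta)
        sign_m, logdet_m = np.linalg.slogdet(Sigma)
        loglik = -0.5 * N * (
            p * np.log(2 * np.pi) + logdet_m + float(np.sum(np.linalg.inv(Sigma) * S_biased))
        )
        aic_val = -2.0 * loglik + 2.0 * ram.q

        # independence baseline (for CFI): diagonal Sigma, closed form
        baseline_chi2 = float((N - 1) * (np.sum(np.log(np.diag(S))) - logdetS))
        baseline_df = p * (p - 1) // 2

        result = FitResult(
            spec=spec,
            identification=self.identification,
            converged=converged,
            N=N,
            p=p,
            df=df,
            n_free=ram.q,
            free_names=list(ram.free_names),
            chi2_ml=chi2_ml,
            loglik=float(loglik),
            aic_=float(aic_val),
            baseline_chi2=baseline_chi2,
            baseline_df=baseline_df,
            heywood_flags=heywood,
            n_iter=int(res.nit),
            grad_norm=grad_norm,
            _theta=theta,
            _model=ram,
            _moments=moments,
        )

        if self.robust and moments.data is not None and converged != "dnc":
            _apply_robust(result)
        else:
            result.sb_scaling = None
            result.chi2_sb = None

        _apply_indices(result, variant=self.index_variant)

        self.result_ = result
        self.spec_ = spec
        self.chi2_ml_ = result.chi2_ml
        self.chi2_sb_ = result.chi2_sb
        self.sb_scaling_ = result.sb_scaling
        self.df_ = result.df
        self.rmsea_ = result.rmsea
        self.cfi_ = result.cfi
        self.aic_ = result.aic_
        self.converged_ = result.converged
        self.n_features_in_ = p
        return self


# --------------------------------------------------------------------------
# robust statistics
# --------------------------------------------------------------------------


def _gamma_adf(data: np.ndarray) -> np.ndarray:
    """Empirical covariance matrix of vech((x-xbar)(x-xbar)') (divisor N)."""
    X = data - data.mean(axis=0)
    N, p = X.shape
    r, c = _vech_indices(p)
    Y = X[:, r] * X[:, c]  # N x p*
    Yc = Y - Y.mean(axis=0)
    return (Yc.T @ Yc) / N


def _normal_theory_V(Sigma: np.ndarray) -> np.ndarray:
    p = Sigma.shape[0]
    D = _duplication(p)
    Si = np.linalg.inv(Sigma)
    return 0.5 * D.T @ np.kron(Si, Si) @ D


def _apply_robust(result: FitResult) -> None:
    """Populate the SB scaling factor, scaled chi2 and sandwich SEs in place."""
    ram, moments = result._model, result._moments
    if moments.data is None:
        raise ValueError("raw data are required for robust statistics")
    theta = result._theta
    Sigma = ram.implied(theta)
    Delta = ram.delta(theta)
    V = _normal_theory_V(Sigma)
    Gamma = _gamma_adf(moments.data)
    VD = V @ Delta
    H = Delta.T @ VD  # information (unit scale)
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; falling back to the naive statistic")
        result.sb_scaling = 1.0
        result.chi2_sb = result.chi2_ml
        return
    U = V - VD @ Hinv @ VD.T
    df = result.df
    if df > 0:
        c = float(np.sum(U * Gamma.T)) / df  # tr(U Gamma) / df
        if not np.isfinite(c) or c <= 0:
            warnings.warn("non-positive scaling factor; falling back to the naive statistic")
            c = 1.0
    else:
        c = 1.0
    result.sb_scaling = c
    result.chi2_sb = result.chi2_ml / c
    acov = Hinv @ VD.T @ Gamma @ VD @ Hinv / moments.N
    result._se_robust = np.sqrt(np.clip(np.diag(acov), 0.0, None))

    # baseline scaling for scaled incremental indices: diagonal model
    p = ram.p
    Delta_b = np.zeros((ram.nstar, p))
    k = 0
    for idx, (i, j) in enumerate(zip(*_vech_indices(p))):
        if i == j:
            Delta_b[idx, k] = 1.0
            k += 1
    Vb = _normal_theory_V(np.diag(np.diag(moments.S)))
    VDb = Vb @ Delta_b
    Ub = Vb - VDb @ np.linalg.inv(Delta_b.T @ VDb) @ VDb.T
    df_b = result.baseline_df
    cb = float(np.sum(Ub * Gamma.T)) / df_b if df_b > 0 else 1.0
    result.baseline_scaling = cb if np.isfinite(cb) and cb > 0 else 1.0


def _apply_indices(result: FitResult, variant: str = "scaled") -> None:
    from .indices import fit_indices

    N = result.N
    rm_ml, cf_ml = fit_indices(
        result.chi2_ml, result.df, N, result.baseline_chi2, result.baseline_df
    )
    result.rmsea_ml, result.cfi_ml = rm_ml, cf_ml
    if variant == "scaled" and result.chi2_sb is not None:
        rm, cf = fit_indices(
            result.chi2_sb,
            result.df,
            N,
            result.baseline_chi2 / result.baseline_scaling,
            result.baseline_df,
        )
        result.rmsea, result.cfi = rm, cf
    else:
        result.rmsea, result.cfi = rm_ml, cf_ml


# --------------------------------------------------------------------------
# modification indices
# --------------------------------------------------------------------------


def _candidate_parameters(result: FitResult) -> list[Parameter]:
    ram = result._model
    spec = result.spec
    present = {p.key() for p in ram.table}
    fixed_zero = {p.key() for p in ram.table if not p.free}
    cands: list[Parameter] = []
    indicators = [v for v in ram.obs]
    for f in spec.latent_factors:
        for v in indicators:
            key = (LOADING, f, v)
            if key not in present or key in fixed_zero:
                cands.append(Parameter(LOADING, f, v))
    for i, a in enumerate(indicators):
        for b in indicators[i + 1:]:
            x, y = sorted((a, b))
            key = (COVARIANCE, x, y)
            if key not in present or key in fixed_zero:
                cands.append(Parameter(COVARIANCE, x, y))
    return cands


def modification_indices(
    result: FitResult, parameters: Iterable[Parameter] | None = None
) -> list[ModIndex]:
    """Univariate score-test indices for fixed/absent parameters, sorted descending.

    Each index estimates the chi-square drop expected if the parameter were
    freed; ``epc`` is the expected parameter change.  Requesting an already
    free parameter raises ``ModelSpecError``.
    """
    if result.converged == "dnc":
        raise RuntimeError("modification indices require a converged fit")
    ram, moments = result._model, result._moments
    free_keys = {ram.table[row].key() for rows in ram.free_members for row in rows}
    if parameters is None:
        parameters = _candidate_parameters(result)
    else:
        parameters = list(parameters)
        for par in parameters:
            if par.key() in free_keys:
                raise ModelSpecError(f"parameter {par.name} is already free")
    theta = result._theta
    S, N = moments.S, moments.N
    Sigma = ram.implied(theta)
    Delta = ram.delta(theta)
    V = _normal_theory_V(Sigma)
    VD = V @ Delta
    H = Delta.T @ VD
    Hinv = np.linalg.inv(H)
    out: list[ModIndex] = []
    for par in parameters:
        if par.key() in free_keys:
            continue
        d_phi, g_phi = ram.candidate_dsigma_grad(par, theta, S)
        v_d = V @ d_phi
        i_pp = float(d_phi @ v_d)
        i_pt = Delta.T @ v_d
        s = i_pp - float(i_pt @ Hinv @ i_pt)
        # a candidate whose profiled information is a sliver of its marginal
        # information is not identified once freed: the score test degenerates
        if i_pp <= 0 or s / i_pp <= 1e-3:
            continue
        mi = (N - 1) * g_phi**2 / (4.0 * s)
        epc = -g_phi / (2.0 * s)
        out.append(ModIndex(parameter=par.name, mi=float(mi), epc=float(epc)))
    out.sort(key=lambda m: m.mi, reverse=True)
    return out


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------


def fit_ml(
    spec: ModelSpec | str,
    data: pd.DataFrame | SampleMoments,
    identification: str = "unit_variance",
    robust: bool = True,
    **kwargs,
) -> FitResult:
    """Fit a model by maximum likelihood; thin wrapper around :class:`SEM`."""
    est = SEM(spec, identification=identification, robust=robust, **kwargs)
    est.fit(data)
    return est.result_


def satorra_bentler(result: FitResult, data: pd.DataFrame | np.ndarray | None = None) -> FitResult:
    """(Re)compute the mean-scaled statistic and sandwich SEs on a fit."""
    if result.converged == "dnc":
        raise RuntimeError("cannot scale a non-converged fit")
    if data is not None:
        X = data[ [v for v in result._model.obs] ].to_numpy() if isinstance(data, pd.DataFrame) else np.asarray(data)
        result._moments.data = X
    if result._moments.data is None:
        raise ValueError("raw data are required for the Satorra-Bentler correction")
    _apply_robust(result)
    _apply_indices(result)
    return result


def implied_covariance(
    spec: ModelSpec | str,
    values: Mapping[str, float],
    identification: str = "unit_variance",
) -> tuple[np.ndarray, list[str]]:
    """Model-implied covariance for fully specified parameter values.

    ``values`` maps free-parameter names (or labels) to numbers; fixed
    parameters use their fixed values.  Returns (Sigma, observed names).
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_text(spec)
    ram = _RAMModel(spec, identification)
    theta = np.zeros(ram.q)
    for k, name in enumerate(ram.free_names):
        if name not in values:
            raise KeyError(f"no value supplied for free parameter {name}")
        theta[k] = float(values[name])
    return ram.implied(theta), list(ram.obs)
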