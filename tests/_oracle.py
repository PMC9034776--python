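"""Independent brute-force oracle for confirmatory factor models.

Deliberately separate from the package's estimation path: the implied
covariance is assembled directly as Lambda Phi Lambda' + Theta, the ML
discrepancy is minimized with numeric gradients, and the robust scaling
factor is computed from finite-difference Jacobians and explicitly looped
fourth moments.  Used only to cross-check the engine in tests.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


class BruteForceCFA:
    """CFA with a fixed loading pattern, free factor correlations and
    residual variances, optional residual covariances; unit factor variances."""

    def __init__(self, pattern: dict[tuple[int, int], bool], p: int, m: int,
                 rescov_pairs: tuple[tuple[int, int], ...] = ()):
        # pattern: (indicator, factor) -> loading present
        self.pattern = sorted(pattern)
        self.p, self.m = p, m
        self.rescov_pairs = rescov_pairs
        self.n_lam = len(self.pattern)
        self.n_phi = m * (m - 1) // 2
        self.n_free = self.n_lam + self.n_phi + p + len(rescov_pairs)

    def sigma(self, x: np.ndarray) -> np.ndarray:
        lam = np.zeros((self.p, self.m))
        for k, (i, j) in enumerate(self.pattern):
            lam[i, j] = x[k]
        phi = np.eye(self.m)
        idx = self.n_lam
        for a in range(self.m):
            for b in range(a + 1, self.m):
                phi[a, b] = phi[b, a] = x[idx]
                idx += 1
        theta = np.diag(np.exp(x[idx: idx + self.p]))
        idx += self.p
        for k, (i, j) in enumerate(self.rescov_pairs):
            theta[i, j] = theta[j, i] = x[idx + k]
        return lam @ phi @ lam.T + theta

    def fml(self, x: np.ndarray, S: np.ndarray, logdetS: float) -> float:
        Sig = self.sigma(x)
        try:
            chol = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2 * np.sum(np.log(np.diag(chol)))
        inv = np.linalg.inv(Sig)
        return float(logdet + np.sum(inv * S) - logdetS - self.p)

    def fit(self, S: np.ndarray, restarts: int = 3, seed: int = 0):
        sign, logdetS = np.linalg.slogdet(S)
        rng = np.random.default_rng(seed)
        sd = np.sqrt(np.diag(S))
        best = None
        for r in range(restarts):
            x0 = np.concatenate([
                0.7 * sd[[i for i, _ in self.pattern]] * (1 + 0.1 * r),
                np.full(self.n_phi, 0.3),
                np.log(0.5 * np.diag(S)),
                np.zeros(len(self.rescov_pairs)),
            ])
            if r:
                x0 = x0 + rng.normal(scale=0.02, size=x0.shape)
            res = optimize.minimize(
                self.fml, x0, args=(S, logdetS), method="BFGS",
                options={"maxiter": 4000, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    # -- robust scaling via finite differences -----------------------------
    def sb_scaling(self, x_hat: np.ndarray, data: np.ndarray, df: int) -> float:
        N, p = data.shape
        Sig = self.sigma(x_hat)
        r, c = np.tril_indices(p)
        eps = 1e-6
        Delta = np.zeros((len(r), self.n_free))
        for k in range(self.n_free):
            xp, xm = x_hat.copy(), x_hat.copy()
            xp[k] += eps
            xm[k] -= eps
            Delta[:, k] = (self.sigma(xp)[r, c] - self.sigma(xm)[r, c]) / (2 * eps)
        # normal-theory weight via explicit duplication matrix
        D = np.zeros((p * p, len(r)))
        for k, (i, j) in enumerate(zip(r, c)):
            D[i * p + j, k] = 1.0
            if i != j:
                D[j * p + i, k] = 1.0
        Si = np.linalg.inv(Sig)
        V = 0.5 * D.T @ np.kron(Si, Si) @ D
        X = data - data.mean(axis=0)
        Y = X[:, r] * X[:, c]
        Yc = Y - Y.mean(axis=0)
        Gamma = Yc.T @ Yc / N
        VD = V @ Delta
        U = V - VD @ np.linalg.inv(Delta.T @ VD) @ VD.T
        return float(np.sum(U * Gamma.T)) / df


def closed_form_one_factor_3(S: np.ndarray) -> np.ndarray:
    """Just-identified 3-indicator loadings from the covariance algebra."""
    l1 = np.sqrt(S[0, 1] * S[0, 2] / S[1, 2])
    l2 = S[0, 1] / l1
    l3 = S[0, 2] / l1
    return np.array([l1, l2, l3])


def factanal_reference(data, n_factors: int = 1):
    """One-factor ML loadings/uniquenesses/objective from R stats::factanal.

    Returns None when Rscript is unavailable.
    """
    import shutil
    import subprocess
    import tempfile
    from pathlib import Path

    if shutil.which("Rscript") is None:
        return None
    with tempfile.TemporaryDirectory() as td:
        csv = Path(td) / "d.csv"
        data.to_csv(csv, index=False)
        script = (
            f'd <- read.csv("{csv}");'
            f'fa <- factanal(d, factors={n_factors}, rotation="none");'
            'cat(unclass(fa$loadings), "\\n");'
            'cat(fa$uniquenesses, "\\n");'
            'cat(fa$criteria["objective"], "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        if out.returncode != 0:
            raise RuntimeError(f"factanal failed: {out.stderr[-500:]}")
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        loadings = np.array([float(v) for v in lines[0].split()])
        uniquenesses = np.array([float(v) for v in lines[1].split()])
        objective = float(lines[2])
        return loadings, uniquenesses, objective
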