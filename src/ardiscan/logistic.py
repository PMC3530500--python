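"""Maximum-likelihood logistic regression via iteratively reweighted least
squares (IRLS).

The fitter is deliberately strict about pathologies that matter for sparse
two-locus cells: rank-deficient designs, degenerate outcomes, and separation
all surface as ``converged=False`` with a diagnostic message rather than as
silently huge coefficients. An optional Firth bias-reduction penalty
(Jeffreys-prior modified score) is available for sparse-cell fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

MAX_ITER = 100
LOGLIK_TOL = 1e-8
#: |beta| beyond this on the logit scale is treated as evidence of separation.
_BETA_BOUND = 30.0


@dataclass
class FitResult:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    message: str = ""
    names: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = LOGLIK_TOL,
    firth: bool = False,
    names: list[str] | None = None,
) -> FitResult:
    """Fit logit P(y=1) = X beta by IRLS.

    ``converged`` is True iff the log-likelihood improvement fell below
    ``tol`` within ``max_iter`` iterations and no pathology was detected.
    The first design column is conventionally the intercept but nothing
    requires it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]

    def failed(msg: str, iters: int = 0) -> FitResult:
        nan = np.full(p, np.nan)
        return FitResult(nan, np.full((p, p), np.nan), np.nan, iters,
                         False, msg, names)

    if n < p + 1:
        return failed(f"too few observations ({n}) for {p} parameters")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        return failed("non-finite values in design or outcome")
    if y.min() == y.max():
        return failed("degenerate outcome: all observations identical")
    if np.linalg.matrix_rank(X) < p:
        return failed("rank-deficient design matrix")

    def information(eta: np.ndarray) -> np.ndarray:
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        return X.T @ (X * w[:, None])

    def objective(eta: np.ndarray) -> float:
        # Firth's penalty is half the log-determinant of the information
        ll = _loglik(y, eta)
        if firth:
            ll += 0.5 * np.linalg.slogdet(information(eta))[1]
        return ll

    beta = np.zeros(p)
    eta = X @ beta
    obj = objective(eta)
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        Xw = X * w[:, None]
        info = X.T @ Xw
        resid = y - mu
        try:
            L = linalg.cho_factor(info)
        except linalg.LinAlgError:
            return failed("information matrix not positive definite", it)
        if firth:
            # modified score: U* = X'(y - mu + h (1/2 - mu)), h = hat values
            h = np.einsum("ij,ij->i", Xw, linalg.cho_solve(L, X.T).T)
            resid = resid + h * (0.5 - mu)
        step = linalg.cho_solve(L, X.T @ resid)
        # step-halving keeps the objective monotone
        obj_new = -np.inf
        for _ in range(12):
            beta_new = beta + step
            eta_new = X @ beta_new
            obj_new = objective(eta_new)
            if obj_new >= obj - 1e-10:
                break
            step = 0.5 * step
        beta, eta = beta_new, eta_new
        if np.abs(beta).max() > _BETA_BOUND:
            return failed("separation suspected: coefficient diverged", it)
        if abs(obj_new - obj) < tol and it > 1:
            try:
                cov = linalg.inv(information(eta))
            except linalg.LinAlgError:
                return failed("singular information at optimum", it)
            return FitResult(beta, cov, _loglik(y, eta), it, True, "", names)
        obj = obj_new
    return failed(f"no convergence in {max_iter} iterations", max_iter)


def likelihood_ratio(full: FitResult, reduced: FitResult) -> float:
    """LRT statistic 2 (logL_full - logL_reduced); NaN if either fit failed."""
    if not (full.converged and reduced.converged):
        return float("nan")
    return max(0.0, 2.0 * (full.loglik - reduced.loglik))
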