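"""Maximum-likelihood logistic regression by IRLS with step-halving.

All association models in the pipeline (per-SNP scan, omnibus haplotype LRT,
haplotype-specific Wald tests) go through :func:`fit_logistic`. The fitter
guarantees a non-decreasing log-likelihood path (Newton steps are halved on
overshoot), reports Wald covariance from the observed information at the
optimum, and flags rather than silently reports fits that fail to converge
(e.g. under complete separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

MAX_ABS_COEF = 30.0  # |log-odds per covariate SD| beyond this is treated as separation


class SingleClassError(ValueError):
    """The outcome vector contains only one class."""


class RankDeficientError(ValueError):
    """The design matrix is not of full column rank."""


@dataclass
class LogisticFit:
    """IRLS fit result on the log-odds scale."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    n_iter: int = 0
    message: str = ""
    loglik_path: list[float] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self, j: int) -> float:
        from scipy.stats import norm

        z = self.coef[j] / self.se()[j]
        return float(2 * norm.sf(abs(z)))

    def or_ci(self, j: int, level: float = 0.95) -> tuple[float, float, float]:
        """Odds ratio and Wald CI ``exp(beta +/- z*SE)`` for coefficient j."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        b, s = self.coef[j], self.se()[j]
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # stable: sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit ``logit P(Y=1|X) = X beta`` by Newton/IRLS.

    Convergence when the max absolute score drops below ``tol_score`` or the
    relative log-likelihood change below ``tol_loglik``. Raises
    :class:`SingleClassError` for a one-class outcome and
    :class:`RankDeficientError` for a rank-deficient design; separation is
    reported via ``converged=False`` with a diagnostic message.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) matching y")
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise SingleClassError("outcome has a single class")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficientError("design matrix is rank deficient")

    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(y, eta)
    path = [ll]
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        score = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        hess = X.T @ (w[:, None] * X)
        try:
            delta = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix (possible separation)"
            break
        # step-halving keeps the loglik path non-decreasing
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-13:
                break
            step /= 2.0
        else:
            message = "step-halving failed"
            break
        beta = beta + step * delta
        eta = X @ beta
        ll_prev, ll = ll, ll_new
        path.append(ll)
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        if abs(ll - ll_prev) < tol_loglik * (abs(ll_prev) + 1e-12):
            converged = True
            break

    # scale-aware divergence check: |beta_j| per SD of X_j, so covariates on
    # small scales (e.g. unit-norm PC scores) are not misflagged; a perfectly
    # fitted outcome (all residuals ~0) is complete separation even though
    # the score converges to zero there
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # intercept / constant columns
    mu_fit = expit(eta)
    separated = np.max(np.abs(beta) * scale) > MAX_ABS_COEF or np.all(
        np.abs(y - mu_fit) < 1e-4
    )
    if converged and separated:
        converged = False
        message = "estimates diverged: complete or quasi-complete separation"
    if not converged and not message:
        message = f"no convergence in {max_iter} iterations (possible separation)"

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return LogisticFit(
        coef=beta,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_used=n,
        n_iter=it,
        message=message,
        loglik_path=path,
    )
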