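"""Maximum-likelihood logistic regression by iteratively reweighted least squares.

One small, fast fitting routine shared by the association, haplotype and
pipeline modules.  Defaults: at most 100 iterations, convergence when the
deviance changes by less than 1e-10, complete/quasi-complete separation
flagged when any coefficient exceeds 15 in absolute value.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import CollinearityError, ConvergenceError

MAX_ABS_BETA = 15.0  # separation heuristic


class LogisticFit:
    """Result of an IRLS fit: coefficients, covariance, log-likelihood."""

    __slots__ = ("beta", "cov", "loglik", "n_iter", "converged", "n_obs")

    def __init__(self, beta, cov, loglik, n_iter, converged, n_obs):
        self.beta = beta
        self.cov = cov
        self.loglik = loglik
        self.n_iter = n_iter
        self.converged = converged
        self.n_obs = n_obs

    @property
    def se(self):
        return np.sqrt(np.diag(self.cov))


def _loglik(y, eta):
    # numerically stable Bernoulli log-likelihood: y*eta - log(1 + e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(X, y, max_iter=100, tol=1e-10, ridge=0.0) -> LogisticFit:
    """Fit logit P(y=1) = X beta by Newton-Raphson / IRLS.

    ``X`` must include the intercept column.  Raises
    :class:`~hapghost.errors.ConvergenceError` (with the coefficient trace)
    on separation or non-convergence, and
    :class:`~hapghost.errors.CollinearityError` when the weighted information
    matrix is numerically singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    # start the intercept at the empirical logit
    pbar = np.clip(y.mean(), 1e-9, 1 - 1e-9)
    beta[0] = np.log(pbar / (1 - pbar)) if np.allclose(X[:, 0], 1.0) else 0.0
    eta = X @ beta
    dev_old = -2.0 * _loglik(y, eta)
    trace = [beta.copy()]
    info = None
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # guard against exactly-zero weights under extreme fitted values
        w = np.maximum(w, 1e-12)
        Xw = X * w[:, None]
        info = X.T @ Xw
        if ridge:
            info = info + ridge * np.eye(p)
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise CollinearityError("singular information matrix in logistic fit") from None
        beta_new = beta + step
        # step-halving to keep the deviance non-increasing
        for _ in range(25):
            eta_new = X @ beta_new
            dev_new = -2.0 * _loglik(y, eta_new)
            if dev_new <= dev_old + 1e-12 or not np.isfinite(dev_new):
                break
            beta_new = (beta + beta_new) / 2.0
        beta, eta = beta_new, X @ beta_new
        trace.append(beta.copy())
        if np.max(np.abs(beta)) > MAX_ABS_BETA:
            raise ConvergenceError(
                "separation suspected: |beta| exceeded "
                f"{MAX_ABS_BETA} at iteration {it}", trace=trace,
            )
        dev_new = -2.0 * _loglik(y, eta)
        if abs(dev_old - dev_new) < tol:
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-12)
            info = X.T @ (X * w[:, None])
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                raise CollinearityError("singular information matrix in logistic fit") from None
            return LogisticFit(beta, cov, -dev_new / 2.0, it, True, n)
        dev_old = dev_new
    raise ConvergenceError(f"logistic fit did not converge in {max_iter} iterations", trace=trace)


def lrt_pvalue(loglik_full, loglik_null, df):
    """Two-sided likelihood-ratio p-value for nested logistic models."""
    from scipy.stats import chi2

    stat = max(2.0 * (loglik_full - loglik_null), 0.0)
    return stat, float(chi2.sf(stat, df))
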