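"""Small dense Newton (IRLS) solver for logistic regression.

Calibration-in-the-large, calibration slope and logistic recalibration are all
one- or two-parameter logistic fits that get re-estimated inside bootstrap and
coverage loops (10^4-10^5 fits per run), so a minimal vectorized solver with
negligible per-call overhead is used.  Its estimates are cross-checked against
statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["fit_logistic", "SeparationError", "ConvergenceError"]

# |linear predictor| beyond which fitted probabilities are numerically 0/1 and
# a still-growing fit is treated as (quasi-)separated.
_ETA_SEP = 30.0


class SeparationError(RuntimeError):
    """Raised when the likelihood is monotone in some direction (perfect or
    quasi-perfect separation), so the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Raised when Newton iterations fail to converge; carries the iteration
    trace in ``args[1]``."""


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | float | None = None,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> np.ndarray:
    """Maximum-likelihood logistic fit of binary ``y`` on design ``X``.

    Parameters
    ----------
    X:
        Design matrix (n, p); include a column of ones for an intercept.
    y:
        Binary outcomes (n,).
    offset:
        Fixed additive term on the linear-predictor scale (used by the
        calibration-in-the-large fit, where the slope on logit(p) is pinned
        at 1 and only an intercept is estimated).

    Returns
    -------
    beta : ndarray (p,)

    Raises
    ------
    SeparationError
        If the outcome is degenerate or the data are separated.
    ConvergenceError
        If Newton iterations do not converge within ``max_iter``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("outcome is single-class; logistic MLE undefined")
    off = np.zeros(n) if offset is None else np.broadcast_to(
        np.asarray(offset, dtype=float), (n,)
    )

    beta = np.zeros(p)
    trace: list[float] = []
    ll = _loglik(X @ beta + off, y)
    for _ in range(max_iter):
        eta = X @ beta + off
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            # singular information: constant predictor or total separation
            raise SeparationError(
                "singular Fisher information (degenerate predictor or separation)"
            ) from None
        # damped Newton: halve until the log-likelihood does not decrease
        shrink = 1.0
        for _h in range(30):
            cand = beta + shrink * step
            ll_new = _loglik(X @ cand + off, y)
            if ll_new >= ll - 1e-12:
                break
            shrink *= 0.5
        beta = beta + shrink * step
        trace.append(ll_new)
        if np.max(np.abs(shrink * step)) < tol * (1.0 + np.max(np.abs(beta))):
            return beta
        ll = ll_new

    eta = X @ beta + off
    if np.max(np.abs(beta)) > 1e3 or np.min(np.abs(eta)) > _ETA_SEP:
        raise SeparationError("fit diverging: data appear separated")
    raise ConvergenceError(
        f"logistic fit did not converge in {max_iter} iterations", trace
    )
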