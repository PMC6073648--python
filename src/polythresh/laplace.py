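"""Posterior approximation by MAP optimization plus a Laplace (Gaussian) expansion.

All Bayesian components in this package (acquisition-trajectory fits,
the hierarchical elasticity regression) share this machinery: the log
posterior is maximized on an unconstrained scale with L-BFGS, the Hessian
at the mode is formed by central differences of the gradient, and
posterior draws are taken from N(mode, H^{-1}).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import approx_fprime, minimize


class FitError(RuntimeError):
    """Optimization or curvature failure; carries a diagnostics payload."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class LaplaceFit:
    """Mode, covariance and diagnostics of a Laplace posterior approximation."""

    mode: np.ndarray
    cov: np.ndarray
    log_post: float
    grad_norm: float
    converged: bool
    n_iter: int

    def draws(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from N(mode, cov), shape (n_draws, n_params)."""
        return rng.multivariate_normal(
            self.mode, self.cov, size=n_draws, method="svd"
        )


def _finite_diff_grad(fun: Callable, x: np.ndarray) -> np.ndarray:
    return approx_fprime(x, fun, np.sqrt(np.finfo(float).eps) * (1.0 + np.abs(x)))


def fit_map_laplace(
    neg_log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    grad: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    maxiter: int = 2000,
    hess_step: float = 1e-4,
) -> LaplaceFit:
    """Maximize the log posterior and expand to a Gaussian at the mode.

    ``grad`` may be analytic; otherwise forward differences are used both
    for the optimizer and (centrally) for the Hessian.  Raises
    :class:`FitError` with diagnostics if the optimizer fails or the
    Hessian is not positive definite after a small jitter.
    """
    x0 = np.asarray(x0, dtype=float)
    g = grad if grad is not None else (lambda x: _finite_diff_grad(neg_log_post, x))
    res = minimize(
        neg_log_post,
        x0,
        jac=g,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8, "maxcor": 30},
    )
    grad_norm = float(np.max(np.abs(g(res.x))))
    if not res.success and grad_norm > 1e-2:
        raise FitError(
            f"MAP optimization did not converge: {res.message}",
            diagnostics={"grad_norm": grad_norm, "n_iter": res.nit, "fun": res.fun},
        )

    k = x0.size
    hess = np.empty((k, k))
    step = hess_step * (1.0 + np.abs(res.x))
    for j in range(k):
        xp, xm = res.x.copy(), res.x.copy()
        xp[j] += step[j]
        xm[j] -= step[j]
        hess[:, j] = (g(xp) - g(xm)) / (2.0 * step[j])
    hess = 0.5 * (hess + hess.T)

    eigvals, eigvecs = np.linalg.eigh(hess)
    floor = max(1e-8, 1e-10 * eigvals.max())
    if eigvals.min() < -1e-4 * abs(eigvals.max()):
        raise FitError(
            "Hessian at the mode is not positive definite",
            diagnostics={
                "eigenvalues": eigvals,
                "grad_norm": grad_norm,
                "n_iter": res.nit,
            },
        )
    cov = (eigvecs / np.maximum(eigvals, floor)) @ eigvecs.T

    return LaplaceFit(
        mode=res.x,
        cov=cov,
        log_post=-float(res.fun),
        grad_norm=grad_norm,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
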