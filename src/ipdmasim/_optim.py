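"""Small derivative-free optimization helpers.

The variance-component objectives in this package are smooth, low
dimensional (1-5 parameters) and cheap to evaluate, so a safeguarded Newton
iteration on central finite differences gives high-precision optima (the
convergence criteria downstream are on the order of 1e-8 in the
parameters, tighter than quasi-Newton codes with forward-difference
gradients reliably deliver).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize

__all__ = ["fd_gradient", "fd_hessian", "newton_minimize", "NewtonResult"]


def _steps(x: np.ndarray, rel: float) -> np.ndarray:
    return rel * (1.0 + np.abs(x))


def fd_gradient(f: Callable, x: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def fd_hessian(f: Callable, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (symmetric by construction)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _steps(x, rel)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / (h[i] * h[i])
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fij = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = fij
    return hess


@dataclass
class NewtonResult:
    x: np.ndarray
    fun: float
    n_iter: int
    converged: bool


def newton_minimize(
    f: Callable,
    x0: np.ndarray,
    param_tol: float = 1e-10,
    max_iter: int = 60,
    grad_rel: float = 1e-6,
    hess_rel: float = 1e-4,
    presolve: bool = False,
) -> NewtonResult:
    """Safeguarded finite-difference Newton minimization.

    Indefinite Hessians are shifted to be positive definite; steps that do
    not decrease the objective are halved (falling back to steepest descent
    if necessary).  Optionally a Nelder-Mead pre-solve supplies a robust
    starting point before the Newton polish.
    """
    x = np.asarray(x0, dtype=float).copy()
    if presolve:
        res = optimize.minimize(
            f, x, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400 * x.size},
        )
        x = np.asarray(res.x, dtype=float)
    fx = f(x)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = fd_gradient(f, x, rel=grad_rel)
        H = fd_hessian(f, x, rel=hess_rel)
        try:
            w, V = np.linalg.eigh(H)
        except np.linalg.LinAlgError:
            break
        floor = max(1e-8, 1e-8 * np.max(np.abs(w))) if w.size else 1e-8
        w = np.maximum(w, floor)
        step = -V @ ((V.T @ g) / w)
        # backtracking line search
        t = 1.0
        improved = False
        for _ in range(40):
            x_new = x + t * step
            f_new = f(x_new)
            if np.isfinite(f_new) and f_new <= fx:
                improved = True
                break
            t *= 0.5
        if not improved:
            # try plain gradient descent before giving up
            gn = np.linalg.norm(g)
            if gn > 0:
                t = 1.0 / (1.0 + gn)
                for _ in range(40):
                    x_new = x - t * g
                    f_new = f(x_new)
                    if np.isfinite(f_new) and f_new < fx:
                        improved = True
                        break
                    t *= 0.5
            if not improved:
                converged = True  # no descent direction left: at a minimum
                break
        delta = np.max(np.abs(x_new - x))
        x, fx = x_new, f_new
        if delta < param_tol * (1.0 + np.max(np.abs(x))):
            converged = True
            break
    return NewtonResult(x=x, fun=fx, n_iter=it, converged=converged)
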