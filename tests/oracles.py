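"""Independent oracle implementations used to validate the estimators.

Everything here is deliberately written by a different route than the
package code: closed-form arithmetic, brute-force optimization over all
latent variables, and dense-grid numerical integration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


# ---------------------------------------------------------------------------
# 2x2 tables


def logor_2x2(a: float, b: float, c: float, d: float):
    """Log odds ratio, mean arm logit and variances from a 2x2 table
    (events_treat, nonevents_treat, events_ctrl, nonevents_ctrl)."""
    g1 = math.log(a * d / (b * c))
    g0 = 0.5 * (math.log(a / b) + math.log(c / d))
    var_g1 = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return g0, g1, var_g1


# ---------------------------------------------------------------------------
# univariate REML random-effects meta-analysis (1-D search)


def uni_reml_negll(tau_sq: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau_sq)
    mu = float(w @ y / w.sum())
    return 0.5 * (
        float(np.log(v + tau_sq).sum())
        + math.log(w.sum())
        + float(w @ (y - mu) ** 2)
    )


def uni_reml_tau_sq(y: np.ndarray, v: np.ndarray, upper: float = 50.0) -> float:
    """Grid scan followed by a bounded refinement of the REML variance."""
    grid = np.linspace(0.0, upper, 2001)
    vals = [uni_reml_negll(t, y, v) for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        uni_reml_negll, args=(y, v), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# GLMM likelihood oracles (aggregated binomial cells; x = -1/2, +1/2)

X_ARMS = np.array([-0.5, 0.5])


def _cells_loglik(eta: np.ndarray, n: np.ndarray, y: np.ndarray) -> float:
    return float((y * eta - n * np.logaddexp(0.0, eta)).sum())


def _binom_const(n: np.ndarray, y: np.ndarray) -> float:
    from scipy.special import gammaln

    mask = n > 0
    return float(
        (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1))[mask].sum()
    )


def _log_joint_m3(u, gamma0, gamma1, Ginv, logdetG, n_j, y_j):
    eta = gamma0 + u[0] + (gamma1 + u[1]) * X_ARMS
    lp = _cells_loglik(eta, n_j, y_j)
    return (
        lp
        - 0.5 * float(u @ Ginv @ u)
        - 0.5 * (2.0 * math.log(2.0 * math.pi) + logdetG)
    )


def _polish_mode_m3(u, gamma0, gamma1, Ginv, n_j, y_j):
    """A few Newton steps on the exact gradient, so the mode is accurate to
    machine precision (the Laplace value is quadratic-insensitive, but the
    1e-10 comparison needs a sharp mode)."""
    B = np.column_stack([np.ones(2), X_ARMS])
    for _ in range(25):
        eta = gamma0 + u[0] + (gamma1 + u[1]) * X_ARMS
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = B.T @ (y_j - n_j * mu) - Ginv @ u
        H = B.T @ (B * (n_j * mu * (1 - mu))[:, None]) + Ginv
        step = np.linalg.solve(H, grad)
        u = u + step
        if np.max(np.abs(step)) < 1e-14:
            break
    return u


def laplace_loglik_m3(n: np.ndarray, y: np.ndarray, gamma0, gamma1, G) -> float:
    """Laplace approximation of the marginal log-likelihood, study by study,
    with modes found by a generic optimizer and the exact curvature formula."""
    Ginv = np.linalg.inv(G)
    logdetG = math.log(np.linalg.det(G))
    total = _binom_const(n, y)
    for j in range(n.shape[0]):
        res = optimize.minimize(
            lambda u: -_log_joint_m3(u, gamma0, gamma1, Ginv, logdetG, n[j], y[j]),
            np.zeros(2),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        u_hat = _polish_mode_m3(res.x, gamma0, gamma1, Ginv, n[j], y[j])
        eta = gamma0 + u_hat[0] + (gamma1 + u_hat[1]) * X_ARMS
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n[j] * mu * (1.0 - mu)
        B = np.column_stack([np.ones(2), X_ARMS])
        H = B.T @ (B * w[:, None]) + Ginv
        h_hat = _log_joint_m3(u_hat, gamma0, gamma1, Ginv, logdetG, n[j], y[j])
        total += h_hat + math.log(2.0 * math.pi) - 0.5 * math.log(np.linalg.det(H))
    return total


def dense_grid_loglik_m3(
    n: np.ndarray, y: np.ndarray, gamma0, gamma1, G, n_grid: int = 201, width: float = 6.0
) -> float:
    """Marginal log-likelihood by dense 2-D trapezoid integration of each
    study's integrand over mode +- ``width`` curvature-based SDs."""
    Ginv = np.linalg.inv(G)
    logdetG = math.log(np.linalg.det(G))
    total = _binom_const(n, y)
    for j in range(n.shape[0]):
        res = optimize.minimize(
            lambda u: -_log_joint_m3(u, gamma0, gamma1, Ginv, logdetG, n[j], y[j]),
            np.zeros(2),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        u_hat = res.x
        eta = gamma0 + u_hat[0] + (gamma1 + u_hat[1]) * X_ARMS
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n[j] * mu * (1.0 - mu)
        B = np.column_stack([np.ones(2), X_ARMS])
        H = B.T @ (B * w[:, None]) + Ginv
        sd = np.sqrt(np.diag(np.linalg.inv(H)))
        u0 = np.linspace(u_hat[0] - width * sd[0], u_hat[0] + width * sd[0], n_grid)
        u1 = np.linspace(u_hat[1] - width * sd[1], u_hat[1] + width * sd[1], n_grid)
        U0, U1 = np.meshgrid(u0, u1, indexing="ij")
        eta0 = gamma0 + U0 + (gamma1 + U1) * X_ARMS[0]
        eta1 = gamma0 + U0 + (gamma1 + U1) * X_ARMS[1]
        lp = (
            y[j, 0] * eta0
            - n[j, 0] * np.logaddexp(0.0, eta0)
            + y[j, 1] * eta1
            - n[j, 1] * np.logaddexp(0.0, eta1)
        )
        quad = (
            Ginv[0, 0] * U0**2 + 2.0 * Ginv[0, 1] * U0 * U1 + Ginv[1, 1] * U1**2
        )
        h = lp - 0.5 * quad - 0.5 * (2.0 * math.log(2.0 * math.pi) + logdetG)
        hmax = h.max()
        integral = np.trapezoid(np.trapezoid(np.exp(h - hmax), u1, axis=1), u0)
        total += hmax + math.log(integral)
    return total


def joint_penalized_beta1_m3(n: np.ndarray, y: np.ndarray, G: np.ndarray):
    """Brute-force nested maximization of the joint penalized log-likelihood
    sum_j log f(y_j | u_j) + log phi(u_j; G) over the fixed effects and all
    study-level random effects simultaneously."""
    K = n.shape[0]
    Ginv = np.linalg.inv(G)

    def neg_joint(par: np.ndarray) -> float:
        gamma0, gamma1 = par[0], par[1]
        u = par[2:].reshape(K, 2)
        total = 0.0
        for j in range(K):
            eta = gamma0 + u[j, 0] + (gamma1 + u[j, 1]) * X_ARMS
            total += _cells_loglik(eta, n[j], y[j])
            total -= 0.5 * float(u[j] @ Ginv @ u[j])
        return -total

    x0 = np.zeros(2 + 2 * K)
    res = optimize.minimize(neg_joint, x0, method="BFGS", options={"gtol": 1e-10, "maxiter": 2000})
    return float(res.x[1])
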