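"""One-stage logistic GLMMs for individual-patient-data meta-analysis.

Two model specifications:

* **random intercept + random slope** (``M3``)::

      logit(p_ij) = (g0 + u0j) + (g1 + u1j) x_ij,   (u0j, u1j) ~ N(0, G)

  with a fully estimated 2x2 between-study covariance ``G``;

* **stratified intercept** (``M4``)::

      logit(p_ij) = g_j + (g1 + u1j) x_ij,          u1j ~ N(0, tau1_sq)

  with one fixed intercept per study and a single random slope variance.

Each model is fit by two engines:

* **PQL** (penalized quasi-likelihood, Breslow-Clayton): iterate a working
  linear mixed model for the linearized response ``z = eta + (y - mu) /
  (mu (1 - mu))`` with weights ``mu (1 - mu)``, estimating the
  variance components of the working model by REML, until all fixed-effect
  and variance parameters change by less than ``param_tol``.

* **AGHQ** (adaptive Gauss-Hermite quadrature): maximize the marginal
  likelihood obtained by integrating the random effects out of each study's
  contribution numerically, with the Hermite grid recentered at each
  study's conditional mode and rescaled by the curvature there.  The
  number of quadrature points per dimension is doubled from 5 (cap 41)
  until the maximized log-likelihood stabilizes, unless fixed explicitly.

Because the exposure is binary, every study reduces to at most two binomial
cells (one per arm); all fitting is done on these aggregated cells, which
is likelihood-identical to the subject-level data and much faster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import optimize, special

from ._optim import fd_hessian, newton_minimize
from .datagen import IPDDataset
from .studyfit import EstimationError
from .twostage import Method, PooledFit

__all__ = [
    "GlmmModel",
    "Engine",
    "GlmmSpec",
    "aggregate_cells",
    "fit_glm_cells",
    "fit_pql",
    "fit_aghq",
    "marginal_loglik",
]

_LARGE = 1e12
# cell designs: rows are the two exposure arms, x coded -1/2 (control), +1/2
X_ARM = np.array([-0.5, 0.5])
X_CELL = np.column_stack([np.ones(2), X_ARM])  # fixed-effect design [1, x]


class GlmmModel(str, Enum):
    M3_RANDOM_INTERCEPT_SLOPE = "M3_random_intercept_slope"
    M4_STRATIFIED_INTERCEPT = "M4_stratified_intercept"


class Engine(str, Enum):
    PQL = "PQL"
    AGHQ = "AGHQ"


@dataclass
class GlmmSpec:
    """Estimation settings for a one-stage fit.

    ``quad_points=None`` selects the quadrature size automatically (AGHQ
    only).  ``fixed_cov`` holds the random-effects covariance fixed instead
    of estimating it: a 2x2 array for the random-intercept model, a scalar
    variance for the stratified model (zero degenerates to an ordinary
    logistic regression) -- used mainly for validation.
    """

    model: GlmmModel
    engine: Engine
    max_iter: int = 100
    param_tol: float = 1e-8
    quad_points: int | None = None
    fixed_cov: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.model = GlmmModel(self.model)
        self.engine = Engine(self.engine)
        if self.param_tol <= 0:
            raise ValueError("param_tol must be > 0")
        if self.quad_points is not None and self.quad_points < 1:
            raise ValueError("quad_points must be >= 1")


# ---------------------------------------------------------------------------
# aggregation and plain logistic fits on cells


def aggregate_cells(data: IPDDataset):
    """Collapse a dataset to per-(study, arm) binomial cells.

    Returns ``(n, y, messages)`` where ``n`` and ``y`` have shape (K, 2)
    (columns: control, treatment); a missing arm appears as ``n = 0`` and
    is reported in ``messages``.
    """
    K = data.n_studies
    n = np.zeros((K, 2))
    y = np.zeros((K, 2))
    arm = (data.x > 0).astype(int)
    np.add.at(n, (data.study_id - 1, arm), 1.0)
    np.add.at(y, (data.study_id - 1, arm), data.y.astype(float))
    messages = [
        f"study {j + 1} contributes a single exposure arm"
        for j in np.nonzero(n.min(axis=1) == 0)[0]
    ]
    return n, y, messages


def fit_glm_cells(n: np.ndarray, y: np.ndarray, model: GlmmModel):
    """Fixed-effects logistic ML fit on aggregated cells (no random effects).

    Returns (coef, cov).  Coefficient order: (g0, g1) for the random-
    intercept layout, (g_1..g_K, g1) for the stratified layout.
    """
    K = n.shape[0]
    rows = []
    counts = []
    events = []
    for j in range(K):
        for c in range(2):
            if n[j, c] > 0:
                if model is GlmmModel.M3_RANDOM_INTERCEPT_SLOPE:
                    rows.append([1.0, X_ARM[c]])
                else:
                    row = np.zeros(K + 1)
                    row[j] = 1.0
                    row[K] = X_ARM[c]
                    rows.append(row)
                counts.append(n[j, c])
                events.append(y[j, c])
    X = np.asarray(rows)
    counts = np.asarray(counts)
    events = np.asarray(events)
    coef = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ coef
        mu = special.expit(eta)
        w = counts * mu * (1.0 - mu)
        score = X.T @ (events - counts * mu)
        info = X.T @ (X * w[:, None])
        step = np.linalg.solve(info, score)
        coef = coef + step
        if np.max(np.abs(step)) < 1e-10 * (1.0 + np.max(np.abs(coef))):
            break
    eta = X @ coef
    mu = special.expit(eta)
    w = counts * mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    return coef, np.linalg.inv(info)


# ---------------------------------------------------------------------------
# working linear mixed model for PQL


def _vech(G: np.ndarray) -> np.ndarray:
    if G.shape[0] == 1:
        return np.array([G[0, 0]])
    return np.array([G[0, 0], G[0, 1], G[1, 1]])


def _g_from_vech(p: np.ndarray, d: int) -> np.ndarray:
    if d == 1:
        return np.array([[p[0]]])
    return np.array([[p[0], p[1]], [p[1], p[2]]])


def _g_from_chol(theta: np.ndarray, d: int) -> np.ndarray:
    if d == 1:
        return np.array([[theta[0] ** 2]])
    L = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
    return L @ L.T


def _lmm_core(G: np.ndarray, z: np.ndarray, w: np.ndarray, model: GlmmModel):
    """REML pieces of the working LMM ``z = X beta + Z u + e``, ``e ~ N(0, W^-1)``.

    ``z``/``w`` have shape (K, 2); missing cells carry ``w = 0`` and are
    ignored.  Returns None when a marginal covariance is not positive
    definite.  The random-effect design per cell is [1, x] for the
    random-intercept model and [x] for the stratified model.
    """
    K = z.shape[0]
    d = G.shape[0]
    B = X_CELL if d == 2 else X_ARM[:, None]  # (2, d)
    S = B @ G @ B.T  # (2, 2) marginal random-effect contribution
    both = (w[:, 0] > 0) & (w[:, 1] > 0)
    invV = np.zeros((K, 2, 2))
    logdetV = np.zeros(K)

    if np.any(both):
        wb = w[both]
        V00 = S[0, 0] + 1.0 / wb[:, 0]
        V11 = S[1, 1] + 1.0 / wb[:, 1]
        V01 = S[0, 1]
        det = V00 * V11 - V01 * V01
        if np.any(det <= 0) or np.any(V00 <= 0):
            return None
        invV[both, 0, 0] = V11 / det
        invV[both, 1, 1] = V00 / det
        invV[both, 0, 1] = invV[both, 1, 0] = -V01 / det
        logdetV[both] = np.log(det)
    for j in np.nonzero(~both)[0]:
        a = 0 if w[j, 0] > 0 else 1
        Vs = S[a, a] + 1.0 / w[j, a]
        if Vs <= 0:
            return None
        invV[j, a, a] = 1.0 / Vs
        logdetV[j] = math.log(Vs)

    # per-study X' V^-1 X and X' V^-1 z with cell design X = [1, x]
    T = np.einsum("ci,kcd,dj->kij", X_CELL, invV, X_CELL)
    q = np.einsum("ci,kcd,kd->ki", X_CELL, invV, z)

    if model is GlmmModel.M3_RANDOM_INTERCEPT_SLOPE:
        A = T.sum(axis=0)
        bvec = q.sum(axis=0)
        detA = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        if detA <= 0:
            return None
        beta = np.linalg.solve(A, bvec)
        logdetA = math.log(detA)
        cov_beta = np.linalg.inv(A)
        eta_fix = np.broadcast_to(X_CELL @ beta, (K, 2))
        slope_idx = 1
    else:
        A = np.zeros((K + 1, K + 1))
        A[np.arange(K), np.arange(K)] = T[:, 0, 0]
        A[np.arange(K), K] = T[:, 0, 1]
        A[K, np.arange(K)] = T[:, 0, 1]
        A[K, K] = T[:, 1, 1].sum()
        bvec = np.concatenate([q[:, 0], [q[:, 1].sum()]])
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return None
        beta = np.linalg.solve(A, bvec)
        cov_beta = np.linalg.inv(A)
        eta_fix = beta[:K, None] + beta[K] * X_ARM[None, :]
        slope_idx = K

    r = np.where(w > 0, z - eta_fix, 0.0)
    rss = float(np.einsum("kc,kcd,kd->", r, invV, r))
    negll = 0.5 * (float(logdetV.sum()) + logdetA + rss)
    GBt = G @ B.T  # (d, 2)
    blup = np.einsum("ic,kcd,kd->ki", GBt, invV, r)  # (K, d)
    eta_new = eta_fix + blup @ B.T
    return {
        "negll": negll,
        "beta": beta,
        "cov_beta": cov_beta,
        "blup": blup,
        "eta": eta_new,
        "slope_idx": slope_idx,
    }


def fit_pql(data: IPDDataset, spec: GlmmSpec) -> PooledFit:
    """Penalized quasi-likelihood fit of a one-stage GLMM.

    Alternates the working-response linearization with a REML fit of the
    working linear mixed model until every fixed-effect and variance
    parameter moves by less than ``spec.param_tol`` (cap ``spec.max_iter``
    iterations).  A fit is flagged non-converged when the iteration cap is
    hit, the estimated random-effects covariance is not positive definite
    (eigenvalue below 1e-8), or the inner REML step fails.
    """
    if spec.engine is not Engine.PQL:
        raise ValueError("spec.engine must be PQL")
    if data.n_studies < 2:
        raise EstimationError("one-stage models need >= 2 studies")
    model = spec.model
    d = 2 if model is GlmmModel.M3_RANDOM_INTERCEPT_SLOPE else 1
    n, ycnt, messages = aggregate_cells(data)
    present = n > 0
    phat = np.where(present, ycnt / np.maximum(n, 1.0), 0.0)
    mu = np.where(present, (ycnt + 0.5) / (n + 1.0), 0.5)
    eta = special.logit(mu)

    fixed = spec.fixed_cov is not None
    if fixed:
        G = np.atleast_2d(np.asarray(spec.fixed_cov, dtype=float))
        if G.shape != (d, d):
            raise ValueError(f"fixed_cov must be {d}x{d} for model {model.value}")
        theta = None
    else:
        theta = (
            np.array([math.sqrt(0.1), 0.0, math.sqrt(0.1)])
            if d == 2
            else np.array([math.sqrt(0.1)])
        )
        G = _g_from_chol(theta, d)

    prev: np.ndarray | None = None
    converged = False
    inner_failed = False
    core = None
    it = 0
    z = w = None
    for it in range(1, spec.max_iter + 1):
        w = np.where(present, n * mu * (1.0 - mu), 0.0)
        z = np.where(present, eta + (phat - mu) / (mu * (1.0 - mu)), 0.0)
        if not fixed:

            def reml_obj(th: np.ndarray) -> float:
                c = _lmm_core(_g_from_chol(th, d), z, w, model)
                return _LARGE if c is None else c["negll"]

            res = newton_minimize(
                reml_obj, theta, param_tol=1e-10, max_iter=60,
                presolve=(it == 1),
            )
            if not np.isfinite(res.fun) or res.fun >= _LARGE:
                inner_failed = True
                messages.append("inner REML failed")
                break
            theta = res.x
            G = _g_from_chol(theta, d)
        core = _lmm_core(G, z, w, model)
        if core is None:
            inner_failed = True
            messages.append("working-model covariance not positive definite")
            break
        eta = core["eta"]
        mu = np.clip(special.expit(eta), 1e-10, 1.0 - 1e-10)
        params = (
            np.concatenate([core["beta"], _vech(G)]) if not fixed else core["beta"]
        )
        if prev is not None and np.max(np.abs(params - prev)) < spec.param_tol:
            converged = True
            break
        prev = params

    if core is None:  # first iteration failed outright
        return PooledFit(
            method=Method.PQL_M3 if d == 2 else Method.PQL_M4,
            beta1_hat=math.nan,
            se_beta1=math.nan,
            tau1_sq_hat=math.nan,
            converged=False,
            n_iter=it,
            messages=messages,
        )
    if not converged and not inner_failed:
        messages.append(f"iteration cap {spec.max_iter} reached")
    if inner_failed:
        converged = False

    if not fixed and converged:
        eigs = np.linalg.eigvalsh(G)
        if eigs.min() < 1e-8:
            converged = False
            messages.append("random-effects covariance not positive definite")

    # SE of tau1_sq from the curvature of the final working REML objective
    se_tau1_sq = math.nan
    if not fixed:

        def negll_nat(p: np.ndarray) -> float:
            c = _lmm_core(_g_from_vech(p, d), z, w, model)
            return _LARGE if c is None else c["negll"]

        try:
            H = fd_hessian(negll_nat, _vech(G))
            if np.all(np.linalg.eigvalsh(H) > 0):
                se_tau1_sq = float(math.sqrt(np.linalg.inv(H)[-1, -1]))
            else:
                messages.append("REML information not positive definite")
        except (np.linalg.LinAlgError, ValueError):
            messages.append("REML information evaluation failed")

    beta = core["beta"]
    idx = core["slope_idx"]
    se_beta1 = float(math.sqrt(core["cov_beta"][idx, idx]))
    if d == 2:
        return PooledFit(
            method=Method.PQL_M3,
            beta1_hat=float(beta[1]),
            se_beta1=se_beta1,
            tau1_sq_hat=float(G[1, 1]),
            se_tau1_sq=se_tau1_sq,
            tau0_sq_hat=float(G[0, 0]),
            tau01_hat=float(G[0, 1]),
            beta0_hat=float(beta[0]),
            converged=converged,
            n_iter=it,
            messages=messages,
        )
    return PooledFit(
        method=Method.PQL_M4,
        beta1_hat=float(beta[idx]),
        se_beta1=se_beta1,
        tau1_sq_hat=float(G[0, 0]),
        se_tau1_sq=se_tau1_sq,
        study_intercepts=np.asarray(beta[: data.n_studies]),
        converged=converged,
        n_iter=it,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite quadrature


def _cell_loglik(eta: np.ndarray, n: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood per study summed over cells, stable in eta:
    y*eta - n*log(1 + exp(eta)) (binomial coefficients added separately)."""
    return (y * eta - n * np.logaddexp(0.0, eta)).sum(axis=-1)


def _inv2(G: np.ndarray):
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    if det <= 0 or G[0, 0] <= 0:
        return None, None
    inv = np.array([[G[1, 1], -G[0, 1]], [-G[1, 0], G[0, 0]]]) / det
    return inv, math.log(det)


def _aghq_study_loglik(
    eta_fix: np.ndarray,
    B: np.ndarray,
    G: np.ndarray,
    n: np.ndarray,
    y: np.ndarray,
    nq: int,
):
    """Per-study AGHQ log marginal likelihood.

    ``eta_fix``: (K, 2) fixed-effect linear predictor per cell; ``B``:
    (2, d) random-effect design per cell; ``G``: (d, d) positive-definite
    covariance.  Returns (sum of study log-likelihoods excluding binomial
    coefficients, modes, all_modes_found).
    """
    K = eta_fix.shape[0]
    d = B.shape[1]
    if d == 2:
        Ginv, logdetG = _inv2(G)
        if Ginv is None:
            return None
    else:
        if G[0, 0] <= 0:
            return None
        Ginv = np.array([[1.0 / G[0, 0]]])
        logdetG = math.log(G[0, 0])
    const_phi = -0.5 * (d * math.log(2.0 * math.pi) + logdetG)

    def h(u: np.ndarray) -> np.ndarray:  # (K, d) -> (K,)
        eta = eta_fix + u @ B.T
        quad = np.einsum("ki,ij,kj->k", u, Ginv, u)
        return _cell_loglik(eta, n, y) + const_phi - 0.5 * quad

    # conditional modes by safeguarded Newton
    u = np.zeros((K, d))
    hu = h(u)
    ok = True
    for _ in range(80):
        eta = eta_fix + u @ B.T
        mu = special.expit(eta)
        grad = (y - n * mu) @ B - u @ Ginv
        W = n * mu * (1.0 - mu)
        H = np.einsum("kc,ci,cj->kij", W, B, B) + Ginv[None, :, :]
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # per-study backtracking
        t = np.ones(K)
        for _ in range(40):
            u_new = u + t[:, None] * step
            h_new = h(u_new)
            bad = h_new < hu - 1e-12
            if not np.any(bad):
                break
            t[bad] *= 0.5
        moved = np.max(np.abs(u_new - u))
        u, hu = u_new, h_new
        if moved < 1e-11:
            break
    else:
        ok = False

    eta = eta_fix + u @ B.T
    mu = special.expit(eta)
    W = n * mu * (1.0 - mu)
    H = np.einsum("kc,ci,cj->kij", W, B, B) + Ginv[None, :, :]

    # Cholesky of the per-study curvature (closed form, d <= 2)
    if d == 2:
        c11 = np.sqrt(H[:, 0, 0])
        c21 = H[:, 1, 0] / c11
        diag2 = H[:, 1, 1] - c21**2
        if np.any(diag2 <= 0):
            return None
        c22 = np.sqrt(diag2)
        logdiagC = np.log(c11) + np.log(c22)
        # (C^-T) upper triangular per study
        CinvT = np.zeros((K, 2, 2))
        CinvT[:, 0, 0] = 1.0 / c11
        CinvT[:, 0, 1] = -c21 / (c11 * c22)
        CinvT[:, 1, 1] = 1.0 / c22
    else:
        c11 = np.sqrt(H[:, 0, 0])
        logdiagC = np.log(c11)
        CinvT = (1.0 / c11)[:, None, None]

    nodes, weights = np.polynomial.hermite.hermgauss(nq)
    if d == 2:
        t1, t2 = np.meshgrid(nodes, nodes, indexing="ij")
        tgrid = np.column_stack([t1.ravel(), t2.ravel()])  # (Q, 2)
        logw = np.add.outer(np.log(weights), np.log(weights)).ravel()
    else:
        tgrid = nodes[:, None]
        logw = np.log(weights)
    tsq = (tgrid**2).sum(axis=1)

    u_nodes = u[:, None, :] + math.sqrt(2.0) * np.einsum(
        "kij,qj->kqi", CinvT, tgrid
    )  # (K, Q, d)
    eta_nodes = eta_fix[:, None, :] + u_nodes @ B.T  # (K, Q, 2)
    quad = np.einsum("kqi,ij,kqj->kq", u_nodes, Ginv, u_nodes)
    log_int = (
        (y[:, None, :] * eta_nodes - n[:, None, :] * np.logaddexp(0.0, eta_nodes)).sum(
            axis=-1
        )
        + const_phi
        - 0.5 * quad
    )
    ll_j = (
        0.5 * d * math.log(2.0)
        - logdiagC
        + special.logsumexp(logw[None, :] + tsq[None, :] + log_int, axis=1)
    )
    return float(ll_j.sum()), u, ok


def _binom_const(n: np.ndarray, y: np.ndarray) -> float:
    return float(
        (special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1))[
            n > 0
        ].sum()
    )


def marginal_loglik(
    data: IPDDataset,
    gamma: np.ndarray,
    G: np.ndarray | float,
    model: GlmmModel | str = GlmmModel.M3_RANDOM_INTERCEPT_SLOPE,
    nq: int = 21,
) -> float:
    """AGHQ approximation of the marginal log-likelihood at given parameters.

    For the random-intercept model ``gamma = (g0, g1)`` and ``G`` is the
    2x2 random-effects covariance; for the stratified model ``gamma``
    holds the K study intercepts followed by the pooled slope and ``G`` is
    the scalar slope variance.  Exposed mainly for validation against
    brute-force integration.
    """
    model = GlmmModel(model)
    n, y, _ = aggregate_cells(data)
    const = _binom_const(n, y)
    gamma = np.asarray(gamma, dtype=float)
    if model is GlmmModel.M3_RANDOM_INTERCEPT_SLOPE:
        eta_fix = np.broadcast_to(X_CELL @ gamma, n.shape)
        out = _aghq_study_loglik(eta_fix, X_CELL, np.atleast_2d(G), n, y, nq)
    else:
        K = data.n_studies
        eta_fix = gamma[:K, None] + gamma[K] * X_ARM[None, :]
        out = _aghq_study_loglik(
            eta_fix, X_ARM[:, None], np.atleast_2d(G), n, y, nq
        )
    if out is None:
        return -math.inf
    return out[0] + const


_NQ_CAP = 41


def _fit_aghq_m3(data: IPDDataset, spec: GlmmSpec, n, ycnt, messages) -> PooledFit:
    K = data.n_studies
    fixed = spec.fixed_cov is not None

    def negll(par: np.ndarray, nq: int) -> float:
        gamma = par[:2]
        G = (
            np.atleast_2d(np.asarray(spec.fixed_cov, dtype=float))
            if fixed
            else _g_from_chol(par[2:], 2) + 1e-10 * np.eye(2)
        )
        eta_fix = np.broadcast_to(X_CELL @ gamma, (K, 2))
        out = _aghq_study_loglik(eta_fix, X_CELL, G, n, ycnt, nq)
        if out is None:
            return _LARGE
        return -out[0]

    # starting values: pooled logistic fit + moment-based covariance from
    # the per-study empirical logits
    coef0, _ = fit_glm_cells(n, ycnt, GlmmModel.M3_RANDOM_INTERCEPT_SLOPE)
    if fixed:
        Gfix = np.atleast_2d(np.asarray(spec.fixed_cov, dtype=float))
        if np.all(Gfix == 0):  # degenerate: ordinary logistic regression
            coef, cov = fit_glm_cells(n, ycnt, spec.model)
            return PooledFit(
                method=Method.AGHQ_M3,
                beta1_hat=float(coef[1]),
                se_beta1=float(math.sqrt(cov[1, 1])),
                tau1_sq_hat=0.0,
                tau0_sq_hat=0.0,
                tau01_hat=0.0,
                beta0_hat=float(coef[0]),
                converged=True,
                n_iter=0,
                messages=messages,
            )
        x0 = coef0
    else:
        el = special.logit((ycnt + 0.5) / (n + 1.0))
        g0j = el.mean(axis=1)
        g1j = el[:, 1] - el[:, 0]
        S = np.cov(np.column_stack([g0j, g1j]).T)
        wS, VS = np.linalg.eigh(0.5 * (S + S.T))
        S = VS @ np.diag(np.maximum(wS, 0.05)) @ VS.T
        L0 = np.linalg.cholesky(S)
        x0 = np.concatenate([coef0, [L0[0, 0], L0[1, 0], L0[1, 1]]])

    nq = spec.quad_points if spec.quad_points is not None else 5
    res = newton_minimize(
        lambda p: negll(p, nq), x0, param_tol=spec.param_tol,
        max_iter=spec.max_iter,
    )
    if spec.quad_points is None:
        while nq < _NQ_CAP:
            nq_next = min(2 * nq, _NQ_CAP)
            res_next = newton_minimize(
                lambda p: negll(p, nq_next), res.x,
                param_tol=spec.param_tol, max_iter=spec.max_iter,
            )
            delta_ll = abs(res_next.fun - res.fun)
            res, nq = res_next, nq_next
            if delta_ll < 1e-4:
                break
    messages.append(f"quadrature points per dimension: {nq}")

    converged = res.converged
    if not converged:
        messages.append("optimizer hit the iteration limit")
    par = res.x
    gamma = par[:2]
    G = (
        np.atleast_2d(np.asarray(spec.fixed_cov, dtype=float))
        if fixed
        else _g_from_chol(par[2:], 2)
    )
    if not fixed and np.linalg.eigvalsh(G).min() < 1e-8:
        converged = False
        messages.append("random-effects covariance not positive definite")

    # mode-finding health at the optimum
    eta_fix = np.broadcast_to(X_CELL @ gamma, (K, 2))
    out = _aghq_study_loglik(eta_fix, X_CELL, G + 1e-10 * np.eye(2), n, ycnt, nq)
    if out is None or not out[2]:
        converged = False
        messages.append("conditional mode finding failed at the optimum")

    # observed-information SEs in natural coordinates
    def negll_nat(p: np.ndarray) -> float:
        Gn = np.array([[p[2], p[3]], [p[3], p[4]]])
        if np.linalg.eigvalsh(Gn).min() <= 0:
            return _LARGE
        eta_f = np.broadcast_to(X_CELL @ p[:2], (K, 2))
        o = _aghq_study_loglik(eta_f, X_CELL, Gn, n, ycnt, nq)
        return _LARGE if o is None else -o[0]

    p_nat = np.array([gamma[0], gamma[1], G[0, 0], G[0, 1], G[1, 1]])
    se_beta1 = math.nan
    se_tau1 = math.nan
    if fixed:
        # only the fixed effects were estimated
        H = fd_hessian(lambda p: negll(np.asarray(p), nq), par[:2])
        if np.all(np.linalg.eigvalsh(H) > 0):
            se_beta1 = float(math.sqrt(np.linalg.inv(H)[1, 1]))
    else:
        try:
            H = fd_hessian(negll_nat, p_nat)
            eig = np.linalg.eigvalsh(H)
            if np.all(eig > 0):
                V = np.linalg.inv(H)
                se_beta1 = float(math.sqrt(V[1, 1]))
                se_tau1 = float(math.sqrt(V[4, 4]))
            else:
                converged = False
                messages.append("observed information not positive definite")
                V = np.linalg.pinv(H)
                if V[1, 1] > 0:
                    se_beta1 = float(math.sqrt(V[1, 1]))
        except (np.linalg.LinAlgError, ValueError):
            converged = False
            messages.append("observed-information evaluation failed")

    return PooledFit(
        method=Method.AGHQ_M3,
        beta1_hat=float(gamma[1]),
        se_beta1=se_beta1,
        tau1_sq_hat=float(G[1, 1]),
        se_tau1_sq=se_tau1,
        tau0_sq_hat=float(G[0, 0]),
        tau01_hat=float(G[0, 1]),
        beta0_hat=float(gamma[0]),
        converged=converged,
        n_iter=res.n_iter,
        messages=messages,
    )


def _m4_profile_negll(
    par: np.ndarray,
    n: np.ndarray,
    ycnt: np.ndarray,
    nq: int,
    starts: np.ndarray,
    natural: bool,
):
    """Profile negative log-likelihood for the stratified model.

    ``par = (g1, l)`` with ``tau1_sq = l**2`` (or ``(g1, tau1_sq)`` when
    ``natural``); each study's fixed intercept is maximized out by a
    bounded scalar search warm-started at ``starts``.
    """
    g1 = par[0]
    tau = par[1] if natural else par[1] ** 2
    if natural and tau <= 0:
        return None
    tau = max(tau, 1e-12)
    K = n.shape[0]
    G = np.array([[tau]])
    total = 0.0
    opts = np.empty(K)
    for j in range(K):
        nj = n[j : j + 1]
        yj = ycnt[j : j + 1]

        def study_negll(gj: float) -> float:
            eta_fix = np.array([[gj + g1 * X_ARM[0], gj + g1 * X_ARM[1]]])
            out = _aghq_study_loglik(eta_fix, X_ARM[:, None], G, nj, yj, nq)
            return _LARGE if out is None else -out[0]

        res = optimize.minimize_scalar(
            study_negll,
            bounds=(starts[j] - 8.0, starts[j] + 8.0),
            method="bounded",
            options={"xatol": 1e-9},
        )
        opts[j] = res.x
        total += res.fun
    return total, opts


def _fit_aghq_m4(data: IPDDataset, spec: GlmmSpec, n, ycnt, messages) -> PooledFit:
    K = data.n_studies
    fixed = spec.fixed_cov is not None
    if fixed and float(np.ravel(spec.fixed_cov)[0]) == 0.0:
        coef, cov = fit_glm_cells(n, ycnt, spec.model)
        return PooledFit(
            method=Method.AGHQ_M4,
            beta1_hat=float(coef[K]),
            se_beta1=float(math.sqrt(cov[K, K])),
            tau1_sq_hat=0.0,
            study_intercepts=coef[:K],
            converged=True,
            n_iter=0,
            messages=messages,
        )

    el = special.logit((ycnt + 0.5) / (n + 1.0))
    starts = el.mean(axis=1)
    g1_start = float(np.mean(el[:, 1] - el[:, 0]))
    tau_start = max(float(np.var(el[:, 1] - el[:, 0])) * 0.5, 0.05)
    state = {"starts": starts.copy()}

    def negll(par: np.ndarray, nq: int) -> float:
        if fixed:
            par = np.array(
                [par[0], math.sqrt(float(np.ravel(spec.fixed_cov)[0]))]
            )
        out = _m4_profile_negll(par, n, ycnt, nq, state["starts"], natural=False)
        if out is None:
            return _LARGE
        state["starts"] = out[1]
        return out[0]

    x0 = (
        np.array([g1_start])
        if fixed
        else np.array([g1_start, math.sqrt(tau_start)])
    )

    def obj(p: np.ndarray, nq: int) -> float:
        if fixed:
            return negll(np.array([p[0]]), nq)
        return negll(p, nq)

    nq = spec.quad_points if spec.quad_points is not None else 5
    res = newton_minimize(
        lambda p: obj(p, nq), x0, param_tol=spec.param_tol, max_iter=spec.max_iter
    )
    if spec.quad_points is None:
        while nq < _NQ_CAP:
            nq_next = min(2 * nq, _NQ_CAP)
            res_next = newton_minimize(
                lambda p: obj(p, nq_next), res.x,
                param_tol=spec.param_tol, max_iter=spec.max_iter,
            )
            delta_ll = abs(res_next.fun - res.fun)
            res, nq = res_next, nq_next
            if delta_ll < 1e-4:
                break
    messages.append(f"quadrature points: {nq}")

    converged = res.converged
    if not converged:
        messages.append("optimizer hit the iteration limit")
    if fixed:
        g1 = float(res.x[0])
        tau1_sq = float(np.ravel(spec.fixed_cov)[0])
    else:
        g1 = float(res.x[0])
        tau1_sq = float(res.x[1] ** 2)
        if tau1_sq < 1e-8:
            converged = False
            messages.append("random-slope variance at the zero boundary")

    out = _m4_profile_negll(
        np.array([g1, math.sqrt(max(tau1_sq, 1e-12))]),
        n, ycnt, nq, state["starts"], natural=False,
    )
    intercepts = out[1] if out is not None else np.full(K, math.nan)

    se_beta1 = math.nan
    se_tau1 = math.nan

    def negll_nat(p: np.ndarray) -> float:
        o = _m4_profile_negll(p, n, ycnt, nq, state["starts"], natural=True)
        return _LARGE if o is None else o[0]

    try:
        if fixed:
            H = fd_hessian(lambda p: obj(np.asarray(p), nq), res.x)
            if np.all(np.linalg.eigvalsh(H) > 0):
                se_beta1 = float(math.sqrt(np.linalg.inv(H)[0, 0]))
        else:
            H = fd_hessian(negll_nat, np.array([g1, tau1_sq]))
            eig = np.linalg.eigvalsh(H)
            if np.all(eig > 0):
                V = np.linalg.inv(H)
                se_beta1 = float(math.sqrt(V[0, 0]))
                se_tau1 = float(math.sqrt(V[1, 1]))
            else:
                converged = False
                messages.append("observed information not positive definite")
    except (np.linalg.LinAlgError, ValueError):
        converged = False
        messages.append("observed-information evaluation failed")

    return PooledFit(
        method=Method.AGHQ_M4,
        beta1_hat=g1,
        se_beta1=se_beta1,
        tau1_sq_hat=tau1_sq,
        se_tau1_sq=se_tau1,
        study_intercepts=np.asarray(intercepts),
        converged=converged,
        n_iter=res.n_iter,
        messages=messages,
    )


def fit_aghq(data: IPDDataset, spec: GlmmSpec) -> PooledFit:
    """Maximum-likelihood fit of a one-stage GLMM by adaptive Gauss-Hermite
    quadrature.

    The marginal likelihood factorizes over studies; each study's integral
    (2-dimensional for the random-intercept model, 1-dimensional for the
    stratified model, whose fixed intercepts are profiled out study by
    study) is approximated on a Hermite grid recentered at the conditional
    mode and rescaled by the curvature there.  With a single quadrature
    point the approximation coincides with the Laplace approximation.
    """
    if spec.engine is not Engine.AGHQ:
        raise ValueError("spec.engine must be AGHQ")
    if data.n_studies < 2:
        raise EstimationError("one-stage models need >= 2 studies")
    n, ycnt, messages = aggregate_cells(data)
    if spec.model is GlmmModel.M3_RANDOM_INTERCEPT_SLOPE:
        return _fit_aghq_m3(data, spec, n, ycnt, messages)
    return _fit_aghq_m4(data, spec, n, ycnt, messages)
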