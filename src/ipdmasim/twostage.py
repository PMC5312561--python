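"""Second-stage pooling of per-study estimates.

Two estimators are provided:

* :func:`pool_dl` — the conventional DerSimonian-Laird univariate
  random-effects meta-analysis of the study log odds ratios: the
  between-study variance ``tau1_sq`` is the non-iterative method-of-moments
  value truncated at zero, and the pooled effect is the inverse-variance
  weighted mean with random-effects weights ``1 / (v_j + tau1_sq)``.

* :func:`pool_bivariate_reml` — a bivariate random-effects model for the
  pairs (intercept, slope): ``(g0j_hat, g1j_hat) ~ N((g0, g1), Sigma + Cj)``
  with ``Cj`` the within-study covariance from the first stage and
  ``Sigma`` the between-study covariance, estimated by restricted maximum
  likelihood with ``Sigma`` parameterized through its Cholesky factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._optim import fd_hessian, newton_minimize
from .datagen import IPDDataset
from .studyfit import EstimationError, StudyEstimate, fit_study_logistic

__all__ = [
    "Method",
    "PooledFit",
    "first_stage",
    "pool_dl",
    "pool_bivariate_reml",
    "bivariate_reml_negll",
]

_LARGE = 1e12


class Method(str, Enum):
    DL = "DL"
    BIVREML = "BIVREML"
    PQL_M3 = "PQL_M3"
    PQL_M4 = "PQL_M4"
    AGHQ_M3 = "AGHQ_M3"
    AGHQ_M4 = "AGHQ_M4"


@dataclass
class PooledFit:
    """One estimator's output on one dataset.

    ``tau0_sq_hat`` / ``tau01_hat`` are populated only by methods that model
    the intercepts as random (bivariate REML, one-stage random-intercept);
    ``study_intercepts`` only by the stratified one-stage model;
    ``se_tau1_sq`` is absent (NaN) for DerSimonian-Laird.
    """

    method: Method
    beta1_hat: float
    se_beta1: float
    tau1_sq_hat: float
    se_tau1_sq: float = math.nan
    tau0_sq_hat: float = math.nan
    tau01_hat: float = math.nan
    beta0_hat: float = math.nan  # pooled intercept, when the method models one
    study_intercepts: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def ci_beta1(self) -> tuple[float, float]:
        """Wald 95% interval for the pooled log odds ratio."""
        half = 1.96 * self.se_beta1
        return (self.beta1_hat - half, self.beta1_hat + half)


def first_stage(data: IPDDataset) -> tuple[list[StudyEstimate], list[str]]:
    """Fit the per-study logistic regressions; unusable studies are dropped
    with a message (single-arm studies cannot contribute a log odds ratio)."""
    estimates: list[StudyEstimate] = []
    messages: list[str] = []
    for j, y, x in data.study_arrays():
        try:
            estimates.append(fit_study_logistic(y, x))
        except EstimationError as exc:
            messages.append(f"study {j} dropped at first stage: {exc}")
    return estimates, messages


# ---------------------------------------------------------------------------
# Model 2: DerSimonian-Laird


def pool_dl(estimates: list[StudyEstimate]) -> PooledFit:
    """DerSimonian-Laird method-of-moments pooling of the log odds ratios."""
    if len(estimates) < 2:
        raise EstimationError("DerSimonian-Laird pooling needs >= 2 studies")
    g1 = np.array([e.gamma1_hat for e in estimates])
    v = np.array([e.var_gamma1 for e in estimates])
    if not (np.all(np.isfinite(g1)) and np.all(np.isfinite(v)) and np.all(v > 0)):
        raise EstimationError("non-finite first-stage estimate or variance")
    w = 1.0 / v
    sw = w.sum()
    mean_fixed = float(w @ g1 / sw)
    q = float(w @ (g1 - mean_fixed) ** 2)
    k = g1.size
    denom = sw - float(w @ w) / sw
    tau1_sq = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (v + tau1_sq)
    beta1 = float(w_star @ g1 / w_star.sum())
    se = float(1.0 / math.sqrt(w_star.sum()))
    return PooledFit(
        method=Method.DL,
        beta1_hat=beta1,
        se_beta1=se,
        tau1_sq_hat=tau1_sq,
        converged=True,
        n_iter=0,
    )


# ---------------------------------------------------------------------------
# Model 1: bivariate REML


def _stack_estimates(estimates: list[StudyEstimate]):
    y = np.array([[e.gamma0_hat, e.gamma1_hat] for e in estimates])
    C = np.array([e.cov for e in estimates])
    return y, C


def bivariate_reml_negll(Sigma: np.ndarray, y: np.ndarray, C: np.ndarray) -> float:
    """Negative REML log-likelihood of the bivariate marginal model.

    ``y`` has shape (K, 2) and ``C`` (K, 2, 2).  The value is finite
    whenever every marginal covariance ``Sigma + Cj`` is positive definite
    (``Sigma`` itself may be indefinite at intermediate iterates); a large
    penalty is returned otherwise.
    """
    V = Sigma[None, :, :] + C
    det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
    if np.any(det <= 1e-300) or np.any(V[:, 0, 0] <= 0):
        return _LARGE
    inv = np.empty_like(V)
    inv[:, 0, 0] = V[:, 1, 1] / det
    inv[:, 1, 1] = V[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -V[:, 0, 1] / det
    A = inv.sum(axis=0)
    b = np.einsum("kij,kj->i", inv, y)
    detA = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if detA <= 0:
        return _LARGE
    mu = np.linalg.solve(A, b)
    r = y - mu
    rss = float(np.einsum("ki,kij,kj->", r, inv, r))
    ll = -0.5 * (float(np.log(det).sum()) + math.log(detA) + rss)
    return -ll


def _mom_start(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Method-of-moments starting covariance: sample covariance of the
    estimates minus the mean within-study covariance, projected to PSD."""
    S = np.cov(y.T) - C.mean(axis=0)
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    w = np.maximum(w, 0.01)
    return V @ np.diag(w) @ V.T


def pool_bivariate_reml(
    estimates: list[StudyEstimate],
    fix_tau0_sq: float | None = None,
    fix_tau01: float | None = None,
) -> PooledFit:
    """REML fit of the bivariate random-effects model.

    ``fix_tau0_sq`` / ``fix_tau01`` hold individual entries of the
    between-study covariance fixed (useful for profiling and for
    cross-checks against univariate meta-analysis); by default the full
    matrix is estimated through its Cholesky factor.
    """
    if len(estimates) < 2:
        raise EstimationError("bivariate pooling needs >= 2 studies")
    y, C = _stack_estimates(estimates)
    messages: list[str] = []
    constrained = fix_tau0_sq is not None or fix_tau01 is not None

    if not constrained:

        def build(theta: np.ndarray) -> np.ndarray:
            L = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
            return L @ L.T

        mom = _mom_start(y, C)
        Lm = np.linalg.cholesky(mom + 1e-8 * np.eye(2))
        starts = [
            np.array([math.sqrt(0.1), 0.0, math.sqrt(0.1)]),
            np.array([Lm[0, 0], Lm[1, 0], Lm[1, 1]]),
        ]
    else:

        def build(theta: np.ndarray) -> np.ndarray:
            t0 = fix_tau0_sq if fix_tau0_sq is not None else theta[0] ** 2
            free = theta[1:] if fix_tau0_sq is None else theta
            t01 = fix_tau01 if fix_tau01 is not None else float(free[0])
            t1 = float(free[-1]) ** 2
            return np.array([[t0, t01], [t01, t1]])

        n_free = (fix_tau0_sq is None) + (fix_tau01 is None) + 1
        starts = [np.full(n_free, math.sqrt(0.1))]

    def objective(theta: np.ndarray) -> float:
        return bivariate_reml_negll(build(theta), y, C)

    best = None
    for x0 in starts:
        res = newton_minimize(
            objective, x0, param_tol=1e-8, max_iter=100, presolve=True
        )
        if best is None or res.fun < best.fun:
            best = res
    Sigma = build(best.x)
    converged = best.converged
    if not converged:
        messages.append("REML optimizer hit the iteration limit")

    # GLS point estimates and fixed-effect covariance at Sigma-hat
    V = Sigma[None, :, :] + C
    det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
    if np.any(det <= 0):
        V = V + 1e-10 * np.eye(2)[None, :, :]
        det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
        messages.append("singular marginal covariance ridged by 1e-10")
        if np.any(det <= 0):
            return PooledFit(
                method=Method.BIVREML,
                beta1_hat=math.nan,
                se_beta1=math.nan,
                tau1_sq_hat=math.nan,
                converged=False,
                n_iter=best.n_iter,
                messages=messages + ["persistent singularity"],
            )
    inv = np.empty_like(V)
    inv[:, 0, 0] = V[:, 1, 1] / det
    inv[:, 1, 1] = V[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -V[:, 0, 1] / det
    A = inv.sum(axis=0)
    mu = np.linalg.solve(A, np.einsum("kij,kj->i", inv, y))
    cov_mu = np.linalg.inv(A)

    # SE of tau1_sq from the REML observed information in natural coordinates
    def negll_natural(p: np.ndarray) -> float:
        S = np.array([[p[0], p[1]], [p[1], p[2]]])
        return bivariate_reml_negll(S, y, C)

    p_hat = np.array([Sigma[0, 0], Sigma[0, 1], Sigma[1, 1]])
    se_tau1_sq = math.nan
    try:
        H = fd_hessian(negll_natural, p_hat)
        w = np.linalg.eigvalsh(H)
        if np.all(w > 0):
            se_tau1_sq = float(math.sqrt(np.linalg.inv(H)[2, 2]))
        else:
            converged = False
            messages.append("REML Hessian not positive definite")
    except (np.linalg.LinAlgError, ValueError):
        converged = False
        messages.append("REML Hessian evaluation failed")

    return PooledFit(
        method=Method.BIVREML,
        beta1_hat=float(mu[1]),
        se_beta1=float(math.sqrt(cov_mu[1, 1])),
        tau1_sq_hat=float(Sigma[1, 1]),
        se_tau1_sq=se_tau1_sq,
        tau0_sq_hat=float(Sigma[0, 0]),
        tau01_hat=float(Sigma[0, 1]),
        beta0_hat=float(mu[0]),
        converged=converged,
        n_iter=best.n_iter,
        messages=messages,
    )
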