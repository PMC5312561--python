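"""First-stage per-study logistic regression.

Each study is reduced to its 2x2 table (events / non-events by arm).  The
logistic model ``logit(p) = gamma0 + gamma1 * x`` with ``x`` coded -1/2, +1/2
is saturated for a binary exposure, so the maximum-likelihood fit has the
closed 2x2-table form: ``gamma1`` is the log odds ratio and ``gamma0`` the
mean of the two arm logits.  The fit is nevertheless computed by iteratively
reweighted least squares (IRLS) on the aggregated binomial cells, with the
closed form retained as a fallback and as an independent check in the test
suite.  Tables with a zero cell receive the Haldane-Anscombe continuity
correction (0.5 added to all four cells) and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StudyEstimate", "EstimationError", "fit_study_logistic", "table_2x2"]


class EstimationError(ValueError):
    """The study cannot be analyzed (single arm or no subjects)."""


@dataclass
class StudyEstimate:
    """Per-study intercept/slope estimates with within-study covariance."""

    gamma0_hat: float
    gamma1_hat: float
    cov: np.ndarray  # 2x2: var(g0), cov(g0,g1); cov(g0,g1), var(g1)
    corrected: bool
    n_subjects: int

    @property
    def var_gamma1(self) -> float:
        return float(self.cov[1, 1])


def table_2x2(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Cells (events_treat, nonevents_treat, events_ctrl, nonevents_ctrl)."""
    y = np.asarray(y)
    x = np.asarray(x)
    treat = x > 0
    a = float(np.sum(y[treat]))
    b = float(np.sum(treat) - a)
    c = float(np.sum(y[~treat]))
    d = float(np.sum(~treat) - c)
    return a, b, c, d


def _closed_form(a: float, b: float, c: float, d: float):
    """ML estimates and covariance from (possibly corrected) 2x2 cells.

    With x = +-1/2: gamma1 = logit_t - logit_c, gamma0 = (logit_t + logit_c)/2.
    The arms are independent, so var(gamma1) = v_t + v_c = 1/a+1/b+1/c+1/d,
    var(gamma0) = (v_t + v_c)/4 and cov = (v_t - v_c)/2.
    """
    logit_t = math.log(a / b)
    logit_c = math.log(c / d)
    v_t = 1.0 / a + 1.0 / b
    v_c = 1.0 / c + 1.0 / d
    g1 = logit_t - logit_c
    g0 = 0.5 * (logit_t + logit_c)
    cov = np.array(
        [
            [0.25 * (v_t + v_c), 0.5 * (v_t - v_c)],
            [0.5 * (v_t - v_c), v_t + v_c],
        ]
    )
    return g0, g1, cov


def _irls(a: float, b: float, c: float, d: float, tol: float = 1e-10, max_iter: int = 50):
    """Newton (= IRLS) fit on the two aggregated binomial cells."""
    n = np.array([c + d, a + b])  # control, treatment
    events = np.array([c, a])
    design = np.array([[1.0, -0.5], [1.0, 0.5]])
    theta = np.zeros(2)
    for _ in range(max_iter):
        eta = design @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1.0 - mu)
        score = design.T @ (events - n * mu)
        info = design.T @ (design * w[:, None])
        step = np.linalg.solve(info, score)
        theta = theta + step
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(theta))):
            eta = design @ theta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = n * mu * (1.0 - mu)
            info = design.T @ (design * w[:, None])
            return theta[0], theta[1], np.linalg.inv(info)
    return None


def fit_study_logistic(y: np.ndarray, x: np.ndarray) -> StudyEstimate:
    """Fit ``logit(p) = gamma0 + gamma1 x`` within one study.

    Raises :class:`EstimationError` if the study is empty or has a single
    exposure arm.  A zero cell triggers the Haldane-Anscombe correction
    (0.5 to every cell) before the closed-form fit, with ``corrected=True``.
    """
    y = np.asarray(y)
    x = np.asarray(x)
    if y.size == 0:
        raise EstimationError("empty study")
    if np.all(x > 0) or np.all(x <= 0):
        raise EstimationError("study has a single exposure arm")
    a, b, c, d = table_2x2(y, x)
    if min(a, b, c, d) == 0.0:
        g0, g1, cov = _closed_form(a + 0.5, b + 0.5, c + 0.5, d + 0.5)
        return StudyEstimate(g0, g1, cov, corrected=True, n_subjects=y.size)
    fit = _irls(a, b, c, d)
    if fit is None:  # IRLS failed; the closed form always exists here
        g0, g1, cov = _closed_form(a, b, c, d)
    else:
        g0, g1, cov = fit
    return StudyEstimate(
        float(g0), float(g1), np.asarray(cov), corrected=False, n_subjects=y.size
    )
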