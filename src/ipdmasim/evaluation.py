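"""Monte-Carlo performance metrics: convergence, bias, MSE/RMSE, coverage.

For a target parameter ``theta`` (the pooled log odds ratio ``beta1`` or
the between-study variance ``tau1_sq``) estimated over ``M`` replicates:

* ``bias = mean(theta_hat) - theta`` over replicates with finite estimates,
  ``abs_bias = |bias|``;
* ``mse = mean((theta_hat - theta)**2)``, ``rmse = sqrt(mse)``;
* Gaussian coverage: a replicate covers the truth iff
  ``|theta_hat - theta| <= 1.96 * SE(theta_hat)`` (boundary counts as
  covered); reported as a percentage over replicates with a usable SE;
* the median and quartiles of the per-replicate absolute error
  ``|theta_hat - theta|`` are reported alongside, since scenario-level
  tables are often summarized by median (p25, p75) cells.

Non-converged replicates are retained in bias/MSE (their estimates are
still data) as long as the estimates are finite; non-finite estimates are
excluded with a count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import ScenarioConfig
from .twostage import Method, PooledFit

__all__ = [
    "bias_mse",
    "gaussian_coverage",
    "i_squared",
    "ParamMetrics",
    "PerformanceSummary",
    "summarize",
    "summaries_to_frame",
    "format_cell",
]


def bias_mse(estimates: np.ndarray, truth: float):
    """(bias, abs_bias, mse, rmse) over the finite entries of ``estimates``."""
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    if est.size == 0:
        raise ValueError("no finite estimates")
    bias = float(est.mean() - truth)
    mse = float(np.mean((est - truth) ** 2))
    return bias, abs(bias), mse, math.sqrt(mse)


def gaussian_coverage(theta_hat: float, se: float, theta: float) -> bool:
    """True iff ``|theta_hat - theta| <= 1.96 * se`` (boundary covered)."""
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    return abs(theta_hat - theta) <= 1.96 * se


def i_squared(tau_sq: float) -> float:
    """Heterogeneity fraction tau^2 / (tau^2 + pi^2 / 3) on the log-odds scale."""
    if tau_sq < 0:
        raise ValueError(f"tau_sq must be >= 0, got {tau_sq}")
    return tau_sq / (tau_sq + math.pi**2 / 3.0)


@dataclass
class ParamMetrics:
    """Monte-Carlo metrics for one target parameter."""

    bias: float
    abs_bias: float
    mse: float
    rmse: float
    coverage_pct: float  # NaN when no replicate provides a usable SE
    n_finite: int
    n_covered: int
    n_with_se: int
    abs_err_median: float
    abs_err_p25: float
    abs_err_p75: float


@dataclass
class PerformanceSummary:
    """All metrics for one (scenario x method) cell."""

    scenario: ScenarioConfig
    method: Method
    n_reps_attempted: int
    n_converged: int
    beta1: ParamMetrics
    tau1_sq: ParamMetrics
    n_nonfinite: int = 0

    @property
    def convergence_pct(self) -> float:
        return 100.0 * self.n_converged / self.n_reps_attempted


def _metrics(est: np.ndarray, se: np.ndarray, truth: float) -> ParamMetrics:
    finite = np.isfinite(est)
    bias, abs_bias, mse, rmse = bias_mse(est[finite], truth)
    err = np.abs(est[finite] - truth)
    p25, med, p75 = np.percentile(err, [25, 50, 75])
    usable = finite & np.isfinite(se) & (se > 0)
    n_with_se = int(usable.sum())
    if n_with_se:
        covered = np.abs(est[usable] - truth) <= 1.96 * se[usable]
        n_cov = int(covered.sum())
        cov_pct = 100.0 * n_cov / n_with_se
    else:
        n_cov, cov_pct = 0, math.nan
    return ParamMetrics(
        bias=bias,
        abs_bias=abs_bias,
        mse=mse,
        rmse=rmse,
        coverage_pct=cov_pct,
        n_finite=int(finite.sum()),
        n_covered=n_cov,
        n_with_se=n_with_se,
        abs_err_median=float(med),
        abs_err_p25=float(p25),
        abs_err_p75=float(p75),
    )


def summarize(fits: list[PooledFit], scenario: ScenarioConfig) -> PerformanceSummary:
    """Aggregate replicate fits of a single method under one scenario.

    All fits must share a method.  Non-converged fits count against the
    convergence rate but their finite estimates still enter bias and MSE;
    coverage of ``tau1_sq`` is only defined for methods that return its SE
    (the DerSimonian-Laird method does not).
    """
    if not fits:
        raise ValueError("no fits to summarize")
    methods = {f.method for f in fits}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in one summary: {sorted(m.value for m in methods)}")
    method = fits[0].method
    b1 = np.array([f.beta1_hat for f in fits])
    se_b1 = np.array([f.se_beta1 for f in fits])
    t1 = np.array([f.tau1_sq_hat for f in fits])
    se_t1 = np.array([f.se_tau1_sq for f in fits])
    n_nonfinite = int(np.sum(~np.isfinite(b1)))
    return PerformanceSummary(
        scenario=scenario,
        method=method,
        n_reps_attempted=len(fits),
        n_converged=sum(f.converged for f in fits),
        beta1=_metrics(b1, se_b1, scenario.beta1),
        tau1_sq=_metrics(t1, se_t1, scenario.tau1_sq),
        n_nonfinite=n_nonfinite,
    )


def format_cell(median: float, p25: float, p75: float, digits: int = 2) -> str:
    """Render the conventional ``median (p25, p75)`` table cell."""
    return f"{median:.{digits}f} ({p25:.{digits}f}, {p75:.{digits}f})"


def summaries_to_frame(summaries: list[PerformanceSummary]) -> pd.DataFrame:
    """One row per (scenario x method x parameter), stable column schema."""
    rows = []
    for s in summaries:
        base = {
            "n_studies": s.scenario.n_studies,
            "total_size": s.scenario.total_size,
            "size_scheme": s.scenario.size_scheme.value,
            "tau0_sq": s.scenario.tau0_sq,
            "tau1_sq": s.scenario.tau1_sq,
            "rho": s.scenario.rho,
            "generation_mode": s.scenario.generation_mode.value,
            "method": s.method.value,
            "n_reps_attempted": s.n_reps_attempted,
            "n_converged": s.n_converged,
            "convergence_pct": s.convergence_pct,
        }
        for name, m, truth in (
            ("beta1", s.beta1, s.scenario.beta1),
            ("tau1_sq", s.tau1_sq, s.scenario.tau1_sq),
        ):
            rows.append(
                {
                    **base,
                    "parameter": name,
                    "truth": truth,
                    "bias": m.bias,
                    "abs_bias": m.abs_bias,
                    "mse": m.mse,
                    "rmse": m.rmse,
                    "coverage_pct": m.coverage_pct,
                    "abs_err_cell": format_cell(
                        m.abs_err_median, m.abs_err_p25, m.abs_err_p75
                    ),
                    "abs_err_median": m.abs_err_median,
                    "abs_err_p25": m.abs_err_p25,
                    "abs_err_p75": m.abs_err_p75,
                }
            )
    return pd.DataFrame(rows)
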