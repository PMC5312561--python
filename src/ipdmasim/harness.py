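"""Experiment orchestration: scenarios x methods x replicates.

Seeding is hierarchical and order-independent: each scenario carries its
own master seed (assigned when the grid is built), and replicate ``r`` of a
scenario draws from the child stream ``SeedSequence([scenario.seed, r])``.
Every requested method is fit to the *same* generated dataset within a
replicate (a paired design), and estimator failures are recorded as
non-converged fits rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datagen import IPDDataset, ScenarioConfig, generate_dataset
from .evaluation import PerformanceSummary, summaries_to_frame, summarize
from .onestage import Engine, GlmmModel, GlmmSpec, fit_aghq, fit_pql
from .twostage import Method, PooledFit, first_stage, pool_bivariate_reml, pool_dl

__all__ = [
    "RunManifest",
    "FITTERS",
    "fit_method",
    "run_replicate",
    "run_experiment",
    "fits_to_frame",
    "dataset_hash",
]


def _fit_dl(data: IPDDataset) -> PooledFit:
    estimates, messages = first_stage(data)
    fit = pool_dl(estimates)
    fit.messages.extend(messages)
    return fit


def _fit_bivreml(data: IPDDataset) -> PooledFit:
    estimates, messages = first_stage(data)
    fit = pool_bivariate_reml(estimates)
    fit.messages.extend(messages)
    return fit


def _one_stage(model: GlmmModel, engine: Engine):
    def fit(data: IPDDataset) -> PooledFit:
        spec = GlmmSpec(model=model, engine=engine)
        if engine is Engine.PQL:
            return fit_pql(data, spec)
        return fit_aghq(data, spec)

    return fit


# method registry; tests may monkeypatch entries to inject failures
FITTERS = {
    Method.DL: _fit_dl,
    Method.BIVREML: _fit_bivreml,
    Method.PQL_M3: _one_stage(GlmmModel.M3_RANDOM_INTERCEPT_SLOPE, Engine.PQL),
    Method.PQL_M4: _one_stage(GlmmModel.M4_STRATIFIED_INTERCEPT, Engine.PQL),
    Method.AGHQ_M3: _one_stage(GlmmModel.M3_RANDOM_INTERCEPT_SLOPE, Engine.AGHQ),
    Method.AGHQ_M4: _one_stage(GlmmModel.M4_STRATIFIED_INTERCEPT, Engine.AGHQ),
}


@dataclass
class RunManifest:
    """A full experiment: grid, method subset, output location.

    Summaries are independent of ``n_workers`` and of scenario ordering
    because all randomness flows through per-(scenario, replicate) seed
    streams.
    """

    grid: list[ScenarioConfig]
    methods: list[Method] = field(
        default_factory=lambda: [Method.DL, Method.PQL_M3]
    )
    out_dir: str | None = None
    n_workers: int = 1

    def __post_init__(self) -> None:
        self.methods = [Method(m) for m in self.methods]
        if not self.methods:
            raise ValueError("methods must be non-empty")
        if not self.grid:
            raise ValueError("grid must be non-empty")


def replicate_rng(scenario: ScenarioConfig, rep_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed), int(rep_index)])
    )


def dataset_hash(data: IPDDataset) -> str:
    """Stable digest of the subject-level data (paired-design check)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.study_id).tobytes())
    h.update(np.ascontiguousarray(data.x).tobytes())
    h.update(np.ascontiguousarray(data.y).tobytes())
    return h.hexdigest()[:16]


def fit_method(data: IPDDataset, method: Method) -> PooledFit:
    """Fit one method, converting estimator exceptions into a
    non-converged :class:`PooledFit` (failures are data, not crashes)."""
    try:
        return FITTERS[Method(method)](data)
    except Exception as exc:  # noqa: BLE001 - failure policy, see module doc
        return PooledFit(
            method=Method(method),
            beta1_hat=math.nan,
            se_beta1=math.nan,
            tau1_sq_hat=math.nan,
            converged=False,
            n_iter=0,
            messages=[f"estimator raised: {type(exc).__name__}: {exc}"],
        )


def run_replicate(
    scenario: ScenarioConfig, rep_index: int, methods: list[Method]
) -> list[PooledFit]:
    """Generate one dataset and fit every requested method to it."""
    data = generate_dataset(scenario, rng=replicate_rng(scenario, rep_index))
    return [fit_method(data, m) for m in methods]


def fits_to_frame(
    fits_by_rep: list[list[PooledFit]], scenario: ScenarioConfig
) -> pd.DataFrame:
    """Flatten replicate fits to one row per (replicate x method)."""
    rows = []
    for rep, fits in enumerate(fits_by_rep):
        for f in fits:
            rows.append(
                {
                    "rep": rep,
                    "method": f.method.value,
                    "beta1_hat": f.beta1_hat,
                    "se_beta1": f.se_beta1,
                    "tau1_sq_hat": f.tau1_sq_hat,
                    "se_tau1_sq": f.se_tau1_sq,
                    "tau0_sq_hat": f.tau0_sq_hat,
                    "tau01_hat": f.tau01_hat,
                    "study_intercepts": ";".join(
                        f"{v:.10g}" for v in f.study_intercepts
                    )
                    if f.study_intercepts is not None
                    else "",
                    "converged": bool(f.converged),
                    "n_iter": f.n_iter,
                    "messages": " | ".join(f.messages),
                }
            )
    return pd.DataFrame(rows)


def _scenario_fits(
    scenario: ScenarioConfig, methods: list[Method], n_workers: int
) -> list[list[PooledFit]]:
    if n_workers == 1:
        return [
            run_replicate(scenario, r, methods) for r in range(scenario.n_reps)
        ]
    return Parallel(n_jobs=n_workers)(
        delayed(run_replicate)(scenario, r, methods)
        for r in range(scenario.n_reps)
    )


def run_experiment(manifest: RunManifest) -> list[PerformanceSummary]:
    """Run the full grid and return one summary per (scenario x method).

    With an ``out_dir``, per-scenario fit tables are checkpointed as CSV
    (``fits_scenario<k>.csv``); a rerun reuses complete checkpoints, so an
    interrupted experiment resumes where it stopped.  The final summary
    table is written as ``summaries.csv``.
    """
    out_dir = manifest.out_dir
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        try:
            with open(probe, "w") as fh:
                fh.write("ok")
            os.remove(probe)
        except OSError as exc:
            raise OSError(f"output directory not writable: {out_dir}") from exc

    summaries: list[PerformanceSummary] = []
    for idx, scenario in enumerate(manifest.grid):
        frame = None
        path = (
            os.path.join(out_dir, f"fits_scenario{idx}.csv")
            if out_dir is not None
            else None
        )
        if path is not None and os.path.exists(path):
            cached = pd.read_csv(path, float_precision="round_trip")
            expected = scenario.n_reps * len(manifest.methods)
            if len(cached) == expected:
                frame = cached
        if frame is None:
            fits_by_rep = _scenario_fits(
                scenario, manifest.methods, manifest.n_workers
            )
            frame = fits_to_frame(fits_by_rep, scenario)
            if path is not None:
                # %.17g guarantees exact float64 roundtrip through text
                frame.to_csv(path, index=False, float_format="%.17g")
        for method in manifest.methods:
            sub = frame[frame["method"] == method.value]
            fits = [
                PooledFit(
                    method=method,
                    beta1_hat=float(row.beta1_hat),
                    se_beta1=float(row.se_beta1),
                    tau1_sq_hat=float(row.tau1_sq_hat),
                    se_tau1_sq=float(row.se_tau1_sq),
                    converged=bool(row.converged),
                )
                for row in sub.itertuples()
            ]
            summaries.append(summarize(fits, scenario))
    if out_dir is not None:
        summaries_to_frame(summaries).to_csv(
            os.path.join(out_dir, "summaries.csv"), index=False
        )
    return summaries
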