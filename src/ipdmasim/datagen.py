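"""Synthetic two-level individual-patient data for binary-outcome meta-analysis.

A dataset is a collection of ``K`` studies, each contributing subjects with a
binary exposure ``x`` (coded -1/2 for control, +1/2 for treatment) and a
binary outcome ``y``.  The outcome probability follows one of two logistic
models:

* *random intercept* mode::

      logit(pi_ij) = (beta0 + b0j) + (beta1 + b1j) * x_ij

  with study effects ``(b0j, b1j)`` drawn from a bivariate normal with
  variances ``tau0_sq``, ``tau1_sq`` and correlation ``rho``;

* *stratified intercept* mode::

      logit(pi_ij) = beta_j + (beta1 + b1j) * x_ij

  with per-study intercepts ``beta_j`` drawn from a uniform distribution
  centred at ``beta0`` whose variance equals ``tau0_sq`` (half-width
  ``sqrt(3 * tau0_sq)``), and ``b1j ~ N(0, tau1_sq)``.

Study sizes are either balanced or imbalanced; in the imbalanced scheme one
quarter of the studies (rounded) are "large" and contain ten times as many
subjects as the remaining "small" studies.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SizeScheme",
    "GenerationMode",
    "ScenarioConfig",
    "IPDDataset",
    "ConfigurationError",
    "InfeasibleScenarioError",
    "build_scenario_grid",
    "read_grid_config",
    "allocate_study_sizes",
    "draw_random_effects",
    "draw_stratified_intercepts",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]


class ConfigurationError(ValueError):
    """An invalid scenario or grid configuration; the message names the field."""


class InfeasibleScenarioError(ValueError):
    """A size allocation that would produce a study with fewer than 1 subject."""


class SizeScheme(str, Enum):
    BALANCED = "balanced"
    IMBALANCED = "imbalanced"


class GenerationMode(str, Enum):
    RANDOM_INTERCEPT = "random_intercept"
    STRATIFIED_INTERCEPT = "stratified_intercept"


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid.

    Parameters
    ----------
    n_studies
        Number of studies ``K`` (>= 2).
    total_size
        Average total number of subjects ``N`` across all studies.
    size_scheme
        ``balanced`` (equal study sizes) or ``imbalanced`` (25% large
        studies with 10x more subjects).
    beta0
        Mean log-odds of the outcome in the control condition at x = 0
        (-0.85 gives a ~30% outcome prevalence).
    beta1
        Pooled treatment effect (log odds ratio).
    tau0_sq, tau1_sq
        Between-study variances of the study effect and of the treatment
        effect.
    rho
        Correlation between the two random effects (ignored in stratified
        mode, where no normal study effect exists).
    generation_mode
        ``random_intercept`` or ``stratified_intercept``.
    n_reps
        Monte-Carlo repetitions planned for this scenario.
    seed
        Master seed for this scenario; replicate ``r`` uses the child
        stream derived from ``(seed, r)``.
    """

    n_studies: int
    total_size: int
    size_scheme: SizeScheme = SizeScheme.BALANCED
    beta0: float = -0.85
    beta1: float = 0.18
    tau0_sq: float = 1.0
    tau1_sq: float = 1.0
    rho: float = 0.5
    generation_mode: GenerationMode = GenerationMode.RANDOM_INTERCEPT
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_scheme", SizeScheme(self.size_scheme))
        object.__setattr__(
            self, "generation_mode", GenerationMode(self.generation_mode)
        )
        if self.n_studies < 2:
            raise ConfigurationError(f"n_studies must be >= 2, got {self.n_studies}")
        if self.total_size < self.n_studies:
            raise ConfigurationError(
                f"total_size must be >= n_studies, got {self.total_size}"
            )
        if self.tau0_sq < 0:
            raise ConfigurationError(f"tau0_sq must be >= 0, got {self.tau0_sq}")
        if self.tau1_sq < 0:
            raise ConfigurationError(f"tau1_sq must be >= 0, got {self.tau1_sq}")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError(f"rho must be in [-1, 1], got {self.rho}")
        if self.n_reps < 1:
            raise ConfigurationError(f"n_reps must be >= 1, got {self.n_reps}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_scheme"] = self.size_scheme.value
        d["generation_mode"] = self.generation_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


@dataclass
class IPDDataset:
    """One generated two-level dataset with its realized study effects.

    ``study_id`` runs 1..K; ``x`` is the exposure coded -1/2 / +1/2 and ``y``
    the binary outcome.  ``true_b0`` holds the realized study-effect
    deviations from ``beta0`` (for stratified generation, the realized
    uniform intercept minus ``beta0``), ``true_b1`` the realized treatment
    effect deviations from ``beta1``.
    """

    study_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    true_b0: np.ndarray
    true_b1: np.ndarray
    scenario: ScenarioConfig

    @property
    def n_studies(self) -> int:
        return self.scenario.n_studies

    def study_arrays(self) -> Iterable[tuple[int, np.ndarray, np.ndarray]]:
        """Yield (study_id, y, x) per study in id order."""
        for j in range(1, self.n_studies + 1):
            mask = self.study_id == j
            yield j, self.y[mask], self.x[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"study_id": self.study_id, "x": self.x, "y": self.y}
        )


def allocate_study_sizes(
    n_studies: int, total_size: int, size_scheme: SizeScheme | str
) -> list[int]:
    """Per-study sample sizes under the balanced or imbalanced scheme.

    Balanced: every study gets ``round(N / K)`` subjects.  Imbalanced:
    ``K_L = round(0.25 K)`` large studies of size ``round(10 s)`` and
    ``K - K_L`` small studies of size ``round(s)`` where
    ``s = N / (K - K_L + 10 K_L)``.  Small studies come first.  Rounding is
    Python's round-half-to-even.
    """
    if n_studies < 2:
        raise ConfigurationError(f"n_studies must be >= 2, got {n_studies}")
    if total_size < n_studies:
        raise ConfigurationError(
            f"total_size must be >= n_studies, got {total_size}"
        )
    scheme = SizeScheme(size_scheme)
    if scheme is SizeScheme.BALANCED:
        size = round(total_size / n_studies)
        sizes = [size] * n_studies
    else:
        n_large = round(0.25 * n_studies)
        n_small = n_studies - n_large
        s = total_size / (n_small + 10 * n_large)
        sizes = [round(s)] * n_small + [round(10 * s)] * n_large
    if min(sizes) < 1:
        raise InfeasibleScenarioError(
            f"allocation for K={n_studies}, N={total_size}, "
            f"scheme={scheme.value} yields a study of size < 1"
        )
    return sizes


def draw_random_effects(
    tau0_sq: float,
    tau1_sq: float,
    rho: float,
    n_studies: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """K iid bivariate-normal pairs (b0j, b1j), mean 0, covariance
    [[tau0_sq, rho*tau0*tau1], [rho*tau0*tau1, tau1_sq]].

    Returns an array of shape (K, 2).  Zero variances give exact zeros.
    """
    if tau0_sq < 0 or tau1_sq < 0:
        raise ConfigurationError("variances must be >= 0")
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho must be in [-1, 1], got {rho}")
    s0, s1 = math.sqrt(tau0_sq), math.sqrt(tau1_sq)
    # explicit Cholesky factor; valid for any rho in [-1, 1] incl. zero variances
    chol = np.array(
        [[s0, 0.0], [rho * s1, s1 * math.sqrt(max(0.0, 1.0 - rho * rho))]]
    )
    z = rng.standard_normal((n_studies, 2))
    return z @ chol.T


def draw_stratified_intercepts(
    beta0: float, tau0_sq: float, n_studies: int, rng: np.random.Generator
) -> np.ndarray:
    """K iid uniform intercepts beta_j with mean beta0 and variance tau0_sq.

    The support is ``beta0 +- sqrt(3 * tau0_sq)`` so the first two moments
    match the normal study effects of the random-intercept mode.
    """
    if tau0_sq < 0:
        raise ConfigurationError(f"tau0_sq must be >= 0, got {tau0_sq}")
    half = math.sqrt(3.0 * tau0_sq)
    if half == 0.0:
        # keep the rng stream aligned across modes regardless of variance
        rng.uniform(0.0, 1.0, size=n_studies)
        return np.full(n_studies, float(beta0))
    return rng.uniform(beta0 - half, beta0 + half, size=n_studies)


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def generate_dataset(
    scenario: ScenarioConfig, rng: np.random.Generator | None = None
) -> IPDDataset:
    """Generate one dataset from the scenario's logistic model.

    Exposure is Bernoulli(0.5) recoded to -1/2 / +1/2; the outcome is
    Bernoulli with probability given by the scenario's generation mode.
    With ``rng=None`` a fresh generator seeded from ``scenario.seed`` is
    used, so identical (scenario, seed) pairs give identical data.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    K = scenario.n_studies
    sizes = allocate_study_sizes(K, scenario.total_size, scenario.size_scheme)

    if scenario.generation_mode is GenerationMode.RANDOM_INTERCEPT:
        effects = draw_random_effects(
            scenario.tau0_sq, scenario.tau1_sq, scenario.rho, K, rng
        )
        b0, b1 = effects[:, 0], effects[:, 1]
    else:
        beta_j = draw_stratified_intercepts(
            scenario.beta0, scenario.tau0_sq, K, rng
        )
        b0 = beta_j - scenario.beta0
        b1 = rng.standard_normal(K) * math.sqrt(scenario.tau1_sq)

    n_total = int(sum(sizes))
    study_id = np.repeat(np.arange(1, K + 1), sizes)
    x = rng.binomial(1, 0.5, size=n_total) - 0.5
    eta = (
        scenario.beta0
        + b0[study_id - 1]
        + (scenario.beta1 + b1[study_id - 1]) * x
    )
    pi = _expit(eta)
    y = (rng.random(n_total) < pi).astype(np.int8)
    return IPDDataset(
        study_id=study_id,
        x=x,
        y=y,
        true_b0=b0,
        true_b1=b1,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# grid construction


def build_scenario_grid(grid_spec: dict, base_seed: int = 0) -> list[ScenarioConfig]:
    """Expand factor lists into the full Cartesian product of scenarios.

    ``grid_spec`` mirrors the simulation-parameter table::

        sizes: [{n_studies: 15, total_size: 500, size_scheme: imbalanced}, ...]
        tau0_sq: [0.05, 1, 4]
        tau1_sq: [0.05, 1, 4]
        rho: [0, 0.5]
        generation_mode: [random_intercept, stratified_intercept]
        beta0: -0.85        # scalar
        beta1: 0.18         # scalar
        n_reps: 1000        # scalar

    The product is taken in lexicographic order over the factor lists as
    given (sizes vary slowest).  Each scenario receives a deterministic
    master seed derived from ``base_seed`` and its position in the grid, so
    a scenario's seed does not depend on how the returned list is later
    reordered or filtered.
    """
    required = ["sizes", "tau0_sq", "tau1_sq", "rho", "generation_mode"]
    for key in required:
        if key not in grid_spec:
            raise ConfigurationError(f"grid_spec is missing factor '{key}'")
        if not grid_spec[key]:
            raise ConfigurationError(f"grid_spec factor '{key}' is empty")
    beta0 = float(grid_spec.get("beta0", -0.85))
    beta1 = float(grid_spec.get("beta1", 0.18))
    n_reps = int(grid_spec.get("n_reps", 1000))

    scenarios: list[ScenarioConfig] = []
    product = itertools.product(
        grid_spec["sizes"],
        grid_spec["tau0_sq"],
        grid_spec["tau1_sq"],
        grid_spec["rho"],
        grid_spec["generation_mode"],
    )
    for idx, (size, t0, t1, rho, mode) in enumerate(product):
        seed = int(
            np.random.SeedSequence([int(base_seed), idx]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        try:
            scenarios.append(
                ScenarioConfig(
                    n_studies=int(size["n_studies"]),
                    total_size=int(size["total_size"]),
                    size_scheme=SizeScheme(size.get("size_scheme", "balanced")),
                    beta0=beta0,
                    beta1=beta1,
                    tau0_sq=float(t0),
                    tau1_sq=float(t1),
                    rho=float(rho),
                    generation_mode=GenerationMode(mode),
                    n_reps=n_reps,
                    seed=seed,
                )
            )
        except ValueError as exc:  # includes ConfigurationError
            raise ConfigurationError(str(exc)) from exc
    return scenarios


def read_grid_config(path: str, base_seed: int = 0) -> list[ScenarioConfig]:
    """Read a YAML grid specification (see :func:`build_scenario_grid`)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return build_scenario_grid(spec, base_seed=base_seed)


# ---------------------------------------------------------------------------
# plain-text persistence


def write_dataset(dataset: IPDDataset, path: str) -> None:
    """Write subject rows to CSV with a JSON sidecar (scenario + effects)."""
    dataset.to_frame().to_csv(path, index=False)
    meta = {
        "scenario": dataset.scenario.to_dict(),
        "true_b0": dataset.true_b0.tolist(),
        "true_b1": dataset.true_b1.tolist(),
    }
    with open(path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_dataset(path: str) -> IPDDataset:
    frame = pd.read_csv(path)
    with open(path + ".meta.json") as fh:
        meta = json.load(fh)
    return IPDDataset(
        study_id=frame["study_id"].to_numpy(dtype=int),
        x=frame["x"].to_numpy(dtype=float),
        y=frame["y"].to_numpy(dtype=np.int8),
        true_b0=np.asarray(meta["true_b0"], dtype=float),
        true_b1=np.asarray(meta["true_b1"], dtype=float),
        scenario=ScenarioConfig.from_dict(meta["scenario"]),
    )
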