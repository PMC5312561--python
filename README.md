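# ipdmasim

A simulation framework for comparing analytic strategies for
**individual-patient-data meta-analysis (IPD-MA) of binary outcomes**: should
the data be pooled in one stage or two, which estimation procedure should fit
the one-stage mixed model, and should study baselines be modelled as random
or stratified?

The package is aimed at biostatisticians and methodologists who want to run
Monte-Carlo comparisons of these estimators under controlled heterogeneity,
study-size and correlation conditions, or to reuse the individual estimators
on their own data.

## The models

Data are two-level: subjects *i* nested in studies *j = 1..K*, with a binary
outcome *Y_ij* and a binary exposure *X_ij* coded −½ (control) / +½
(treatment).  Datasets are generated from a logistic model with either
**random study effects**

    logit(π_ij) = (β₀ + b₀ⱼ) + (β₁ + b₁ⱼ) x_ij,   (b₀ⱼ, b₁ⱼ) ~ N(0, Σ),

with Σ = [[τ₀², ρτ₀τ₁], [ρτ₀τ₁, τ₁²]], or with **stratified study effects**,
where each study's intercept βⱼ is drawn from a uniform distribution centred
at β₀ with variance τ₀² and only the treatment effect is random.  β₁ is the
pooled treatment log odds ratio; τ₁² is the between-study heterogeneity of
the treatment effect, which maps to I² = τ₁²/(τ₁² + π²/3) on the log-odds
scale (τ₁² = 1 → I² ≈ 0.23).

Estimators (all return the pooled log OR, its SE, and τ̂₁²):

| method | approach | description |
|---|---|---|
| `DL` | two-stage | per-study logistic fits, then DerSimonian–Laird method-of-moments pooling |
| `BIVREML` | two-stage | bivariate random-effects model for (intercept, slope) pairs, REML |
| `PQL_M3` / `AGHQ_M3` | one-stage | GLMM with correlated random intercept + slope, fit by penalized quasi-likelihood or adaptive Gauss–Hermite quadrature |
| `PQL_M4` / `AGHQ_M4` | one-stage | GLMM with one fixed intercept per study and a random slope |

The evaluation module computes Monte-Carlo bias, MSE/RMSE, Gaussian (Wald)
coverage with the 1.96 rule, and numerical convergence rates per
(scenario × method); the harness orchestrates scenario grids with
hierarchical, order-independent seeding.

## Worked example

```python
from ipdmasim import (ScenarioConfig, generate_dataset, first_stage,
                      pool_dl, fit_pql, GlmmSpec)

scenario = ScenarioConfig(
    n_studies=15, total_size=3000, size_scheme="imbalanced",
    beta0=-0.85, beta1=0.18, tau0_sq=1.0, tau1_sq=1.0, rho=0.5, seed=42,
)
data = generate_dataset(scenario)

dl = pool_dl(first_stage(data)[0])
pql = fit_pql(data, GlmmSpec(model="M3_random_intercept_slope", engine="PQL"))
print(dl.beta1_hat, dl.se_beta1, dl.tau1_sq_hat)
print(pql.beta1_hat, pql.se_beta1, pql.tau1_sq_hat)
```

prints

```
0.3235311192616483 0.19170288996150434 0.3210387167056362
0.2320907619654069 0.23826535431990709 0.653279971818409
```

i.e. on this dataset (true β₁ = 0.18, τ₁² = 1) the two-stage DL estimate of
the pooled log OR is 0.32 with SE 0.19 and a between-study variance estimate
of 0.32, while the one-stage PQL fit gives 0.23 ± 0.24 with τ̂₁² = 0.65 —
both within sampling error of the truth, with DL underestimating the
heterogeneity more severely.  The `examples/` directory contains narrative
scripts for each capability (data generation, two-stage pooling, one-stage
GLMMs, and a small Monte-Carlo experiment).

A thin CLI mirrors the harness:

```bash
ipdmasim run examples/grid_small.yaml --methods DL,PQL_M3 --reps 100 --out-dir out/
ipdmasim summarize out/ examples/grid_small.yaml
```

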