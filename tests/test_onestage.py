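import math

import numpy as np
import pytest

from ipdmasim import (
    GlmmSpec,
    ScenarioConfig,
    fit_aghq,
    fit_glm_cells,
    fit_pql,
    generate_dataset,
    marginal_loglik,
)
from ipdmasim.datagen import IPDDataset
from ipdmasim.onestage import GlmmModel, aggregate_cells
from oracles import (
    dense_grid_loglik_m3,
    joint_penalized_beta1_m3,
    laplace_loglik_m3,
)

M3 = "M3_random_intercept_slope"
M4 = "M4_stratified_intercept"


def relabeled(data: IPDDataset, perm: np.ndarray) -> IPDDataset:
    """Apply a study relabeling: new id of old study j is perm[j-1]+1."""
    return IPDDataset(
        study_id=perm[data.study_id - 1] + 1,
        x=data.x,
        y=data.y,
        true_b0=data.true_b0,
        true_b1=data.true_b1,
        scenario=data.scenario,
    )


def flipped(data: IPDDataset) -> IPDDataset:
    return IPDDataset(
        study_id=data.study_id,
        x=-data.x,
        y=data.y,
        true_b0=data.true_b0,
        true_b1=data.true_b1,
        scenario=data.scenario,
    )


class TestDegenerateLimits:
    def test_pql_with_zero_variance_equals_pooled_glm(self, tiny_dataset):
        fit = fit_pql(
            tiny_dataset,
            GlmmSpec(model=M3, engine="PQL", fixed_cov=np.zeros((2, 2))),
        )
        n, y, _ = aggregate_cells(tiny_dataset)
        coef, cov = fit_glm_cells(n, y, GlmmModel.M3_RANDOM_INTERCEPT_SLOPE)
        assert fit.beta1_hat == pytest.approx(coef[1], abs=1e-6)
        assert fit.beta0_hat == pytest.approx(coef[0], abs=1e-6)
        assert fit.se_beta1 == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-6)

    def test_pooled_glm_agrees_with_statsmodels(self, tiny_dataset):
        sm = pytest.importorskip("statsmodels.api")
        n, y, _ = aggregate_cells(tiny_dataset)
        coef, _ = fit_glm_cells(n, y, GlmmModel.M3_RANDOM_INTERCEPT_SLOPE)
        X = np.column_stack([np.ones_like(tiny_dataset.x), tiny_dataset.x])
        ref = sm.GLM(
            tiny_dataset.y, X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(coef, ref.params, atol=1e-6)

    def test_aghq_m4_with_zero_variance_equals_stratified_glm(self, tiny_dataset):
        fit = fit_aghq(
            tiny_dataset, GlmmSpec(model=M4, engine="AGHQ", fixed_cov=0.0)
        )
        n, y, _ = aggregate_cells(tiny_dataset)
        coef, cov = fit_glm_cells(n, y, GlmmModel.M4_STRATIFIED_INTERCEPT)
        K = tiny_dataset.n_studies
        assert fit.beta1_hat == pytest.approx(coef[K], abs=1e-6)
        np.testing.assert_allclose(fit.study_intercepts, coef[:K], atol=1e-6)
        assert fit.se_beta1 == pytest.approx(math.sqrt(cov[K, K]), abs=1e-6)


class TestQuadratureAccuracy:
    GAMMA = (-0.85, 0.18)
    G = np.array([[0.5, 0.2], [0.2, 0.8]])

    def test_one_node_equals_laplace(self, tiny_dataset):
        n, y, _ = aggregate_cells(tiny_dataset)
        ll_1pt = marginal_loglik(
            tiny_dataset, self.GAMMA, self.G, model=M3, nq=1
        )
        ll_lap = laplace_loglik_m3(n, y, *self.GAMMA, self.G)
        assert ll_1pt == pytest.approx(ll_lap, abs=1e-10)

    def test_dense_grid_integration_at_41_points(self, tiny_dataset):
        # maximize the fixed effects at a held (interior) covariance: with
        # K=3 the ML covariance sits on the boundary, where a singular
        # density would be improper for both integrators
        fit = fit_aghq(
            tiny_dataset,
            GlmmSpec(model=M3, engine="AGHQ", quad_points=41, fixed_cov=self.G),
        )
        gamma = (fit.beta0_hat, fit.beta1_hat)
        n, y, _ = aggregate_cells(tiny_dataset)
        ll_aghq = marginal_loglik(tiny_dataset, gamma, self.G, model=M3, nq=41)
        ll_dense = dense_grid_loglik_m3(n, y, gamma[0], gamma[1], self.G)
        assert ll_aghq == pytest.approx(ll_dense, abs=1e-5)

    def test_quadrature_refinement_is_monotone_stable(self):
        """Doubling the node count changes the log-likelihood by
        decreasing amounts on fixed data."""
        for seed in range(20):
            sc = ScenarioConfig(
                n_studies=3, total_size=30, beta0=-0.85, beta1=0.18,
                tau0_sq=1.0, tau1_sq=1.0, rho=0.5, seed=3000 + seed,
            )
            d = generate_dataset(sc)
            lls = [
                marginal_loglik(d, self.GAMMA, self.G, model=M3, nq=q)
                for q in (5, 10, 20, 40)
            ]
            diffs = [abs(lls[i + 1] - lls[i]) for i in range(3)]
            assert diffs[1] <= diffs[0] + 1e-9
            assert diffs[2] <= diffs[1] + 1e-9


class TestPqlAgainstOracle:
    def test_tiny_dataset_close_to_joint_penalized_oracle(self):
        sc = ScenarioConfig(
            n_studies=3, total_size=30, beta0=-0.3, beta1=0.3,
            tau0_sq=0.5, tau1_sq=0.5, rho=0.3, seed=52,
        )
        d = generate_dataset(sc)
        fit = fit_pql(d, GlmmSpec(model=M3, engine="PQL"))
        n, y, _ = aggregate_cells(d)
        G = np.array(
            [[fit.tau0_sq_hat, fit.tau01_hat], [fit.tau01_hat, fit.tau1_sq_hat]]
        ) + 1e-8 * np.eye(2)
        beta1_oracle = joint_penalized_beta1_m3(n, y, G)
        assert abs(fit.beta1_hat - beta1_oracle) <= 0.05

    def test_duplicating_studies_shrinks_se(self, tiny_dataset):
        d = tiny_dataset
        doubled = IPDDataset(
            study_id=np.concatenate([d.study_id, d.study_id + d.n_studies]),
            x=np.concatenate([d.x, d.x]),
            y=np.concatenate([d.y, d.y]),
            true_b0=np.concatenate([d.true_b0, d.true_b0]),
            true_b1=np.concatenate([d.true_b1, d.true_b1]),
            scenario=ScenarioConfig(
                **{**d.scenario.to_dict(), "n_studies": 2 * d.n_studies,
                   "total_size": 2 * d.scenario.total_size}
            ),
        )
        spec = GlmmSpec(model=M3, engine="PQL")
        fit = fit_pql(d, spec)
        fit2 = fit_pql(doubled, spec)
        assert fit2.se_beta1 < fit.se_beta1
        assert fit2.beta1_hat == pytest.approx(fit.beta1_hat, abs=0.05)


class TestEngineAgreement:
    def test_pql_and_aghq_agree_on_large_balanced_data(self, medium_dataset):
        pql = fit_pql(medium_dataset, GlmmSpec(model=M3, engine="PQL"))
        aghq = fit_aghq(medium_dataset, GlmmSpec(model=M3, engine="AGHQ"))
        assert abs(pql.beta1_hat - aghq.beta1_hat) < 0.1


class TestSymmetries:
    def test_exposure_flip_negates_effect(self, tiny_dataset):
        spec = GlmmSpec(model=M3, engine="PQL")
        fit = fit_pql(tiny_dataset, spec)
        fit_f = fit_pql(flipped(tiny_dataset), spec)
        assert fit_f.beta1_hat == pytest.approx(-fit.beta1_hat, abs=1e-6)
        assert fit_f.tau1_sq_hat == pytest.approx(fit.tau1_sq_hat, abs=1e-6)

    def test_study_relabeling_invariance(self, tiny_dataset):
        rng = np.random.default_rng(0)
        perm = rng.permutation(tiny_dataset.n_studies)
        data_p = relabeled(tiny_dataset, perm)
        spec = GlmmSpec(model=M3, engine="PQL")
        fit = fit_pql(tiny_dataset, spec)
        fit_p = fit_pql(data_p, spec)
        assert fit_p.beta1_hat == pytest.approx(fit.beta1_hat, abs=1e-8)
        # likelihood itself is label-invariant
        G = np.array([[0.5, 0.2], [0.2, 0.8]])
        ll = marginal_loglik(tiny_dataset, (-0.85, 0.18), G, model=M3, nq=11)
        ll_p = marginal_loglik(data_p, (-0.85, 0.18), G, model=M3, nq=11)
        assert ll_p == pytest.approx(ll, abs=1e-8)


class TestSpecValidation:
    def test_engine_mismatch_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            fit_pql(tiny_dataset, GlmmSpec(model=M3, engine="AGHQ"))
        with pytest.raises(ValueError):
            fit_aghq(tiny_dataset, GlmmSpec(model=M3, engine="PQL"))

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            GlmmSpec(model=M3, engine="PQL", param_tol=0.0)
        with pytest.raises(ValueError):
            GlmmSpec(model=M3, engine="AGHQ", quad_points=0)
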