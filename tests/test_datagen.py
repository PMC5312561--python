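import math

import numpy as np
import pytest

from ipdmasim import (
    ConfigurationError,
    GenerationMode,
    InfeasibleScenarioError,
    ScenarioConfig,
    allocate_study_sizes,
    build_scenario_grid,
    draw_random_effects,
    draw_stratified_intercepts,
    generate_dataset,
    read_dataset,
    write_dataset,
)

GRID = {
    "sizes": [
        {"n_studies": 5, "total_size": 500, "size_scheme": "balanced"},
        {"n_studies": 15, "total_size": 500, "size_scheme": "balanced"},
        {"n_studies": 15, "total_size": 3000, "size_scheme": "balanced"},
        {"n_studies": 5, "total_size": 500, "size_scheme": "imbalanced"},
        {"n_studies": 15, "total_size": 500, "size_scheme": "imbalanced"},
        {"n_studies": 15, "total_size": 3000, "size_scheme": "imbalanced"},
    ],
    "tau0_sq": [0.05, 1, 4],
    "tau1_sq": [0.05, 1, 4],
    "rho": [0, 0.5],
    "generation_mode": ["random_intercept", "stratified_intercept"],
}


class TestGrid:
    def test_full_cross_of_factors(self):
        grid = build_scenario_grid(GRID, base_seed=3)
        assert len(grid) == 6 * 3 * 3 * 2 * 2  # 216

    def test_singleton_factors_give_one_scenario(self):
        spec = {
            "sizes": [{"n_studies": 5, "total_size": 500}],
            "tau0_sq": [1],
            "tau1_sq": [1],
            "rho": [0.5],
            "generation_mode": ["random_intercept"],
        }
        grid = build_scenario_grid(spec)
        assert len(grid) == 1
        assert grid[0].generation_mode is GenerationMode.RANDOM_INTERCEPT

    def test_empty_factor_rejected(self):
        spec = dict(GRID, rho=[])
        with pytest.raises(ConfigurationError, match="rho"):
            build_scenario_grid(spec)

    def test_invalid_factor_value_names_field(self):
        spec = dict(GRID, tau0_sq=[-1.0])
        with pytest.raises(ConfigurationError, match="tau0_sq"):
            build_scenario_grid(spec)

    def test_seeds_attached_at_build_time(self):
        g1 = build_scenario_grid(GRID, base_seed=5)
        g2 = build_scenario_grid(GRID, base_seed=5)
        assert [s.seed for s in g1] == [s.seed for s in g2]
        assert len({s.seed for s in g1}) == len(g1)


class TestAllocation:
    @pytest.mark.parametrize(
        "k,n,scheme,expected",
        [
            (5, 500, "imbalanced", [36] * 4 + [357]),
            (15, 500, "imbalanced", [10] * 11 + [98] * 4),
            (15, 3000, "imbalanced", [59] * 11 + [588] * 4),
            (15, 500, "balanced", [33] * 15),
            (5, 500, "balanced", [100] * 5),
        ],
    )
    def test_published_size_layouts(self, k, n, scheme, expected):
        assert allocate_study_sizes(k, n, scheme) == expected

    def test_infeasible_allocation_raises(self):
        with pytest.raises(InfeasibleScenarioError):
            allocate_study_sizes(10, 10, "imbalanced")


class TestRandomEffects:
    def test_zero_variance_gives_exact_zeros(self):
        rng = np.random.default_rng(0)
        eff = draw_random_effects(0.0, 0.0, 0.5, 50, rng)
        assert np.all(eff == 0.0)

    def test_large_sample_covariance(self):
        rng = np.random.default_rng(1)
        eff = draw_random_effects(4.0, 4.0, 0.5, 10_000, rng)
        cov = np.cov(eff.T)
        # SE of a sample covariance of bivariate normals ~ sqrt((c^2+v0 v1)/K)
        se_cov = math.sqrt((2.0**2 + 16.0) / 10_000)
        assert abs(cov[0, 1] - 2.0) < 3 * se_cov
        assert abs(cov[0, 0] - 4.0) < 3 * math.sqrt(2 * 16.0 / 10_000)

    def test_zero_correlation_independent(self):
        rng = np.random.default_rng(2)
        eff = draw_random_effects(1.0, 1.0, 0.0, 10_000, rng)
        corr = np.corrcoef(eff.T)[0, 1]
        assert abs(corr) < 3 / math.sqrt(10_000)


class TestStratifiedIntercepts:
    def test_degenerate_uniform(self):
        rng = np.random.default_rng(3)
        b = draw_stratified_intercepts(-0.85, 0.0, 20, rng)
        assert np.all(b == -0.85)

    def test_moments_match_target(self):
        rng = np.random.default_rng(4)
        k = 20_000
        b = draw_stratified_intercepts(-0.85, 1.0, k, rng)
        assert abs(b.mean() + 0.85) < 3 / math.sqrt(k)
        # var of the sample variance of a uniform: (m4 - sigma^4)/k = 0.8/k
        assert abs(b.var(ddof=1) - 1.0) < 3 * math.sqrt(0.8 / k)

    def test_support_bound(self):
        rng = np.random.default_rng(5)
        b = draw_stratified_intercepts(-0.85, 1.0, 5000, rng)
        half = math.sqrt(3.0)
        assert np.all(b >= -0.85 - half) and np.all(b <= -0.85 + half)


class TestGenerateDataset:
    def test_prevalence_matches_inverse_logit(self):
        sc = ScenarioConfig(
            n_studies=2, total_size=100_000, beta1=0.0,
            tau0_sq=0.0, tau1_sq=0.0, rho=0.0, seed=10,
        )
        d = generate_dataset(sc)
        p = 1.0 / (1.0 + math.exp(0.85))  # 0.2994: prints as 30%
        assert abs(d.y.mean() - p) < 3 * math.sqrt(p * (1 - p) / 100_000)

    def test_null_effect_gives_equal_arm_rates(self):
        sc = ScenarioConfig(
            n_studies=2, total_size=100_000, beta1=0.0,
            tau0_sq=0.0, tau1_sq=0.0, rho=0.0, seed=11,
        )
        d = generate_dataset(sc)
        treat = d.x > 0
        p = 1.0 / (1.0 + math.exp(0.85))
        diff = d.y[treat].mean() - d.y[~treat].mean()
        assert abs(diff) < 3 * math.sqrt(2 * p * (1 - p) / 50_000)

    def test_exposure_code_centers_at_zero(self):
        sc = ScenarioConfig(n_studies=2, total_size=100_000, seed=12)
        d = generate_dataset(sc)
        assert set(np.unique(d.x)) == {-0.5, 0.5}
        assert abs(d.x.mean()) < 3 * 0.5 / math.sqrt(100_000)

    def test_pooled_log_odds_ratio_converges_to_beta1(self):
        sc = ScenarioConfig(
            n_studies=2, total_size=100_000, beta1=0.18,
            tau0_sq=0.0, tau1_sq=0.0, rho=0.0, seed=13,
        )
        d = generate_dataset(sc)
        treat = d.x > 0
        a = d.y[treat].sum()
        b = treat.sum() - a
        c = d.y[~treat].sum()
        e = (~treat).sum() - c
        logor = math.log(a * e / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / e)
        assert abs(logor - 0.18) < 3 * se

    def test_determinism_same_seed_same_data(self):
        sc = ScenarioConfig(n_studies=5, total_size=200, seed=99)
        d1 = generate_dataset(sc)
        d2 = generate_dataset(sc)
        assert np.array_equal(d1.x, d2.x)
        assert np.array_equal(d1.y, d2.y)
        assert np.array_equal(d1.true_b0, d2.true_b0)
        assert np.array_equal(d1.true_b1, d2.true_b1)

    def test_stratified_mode_carries_realized_intercepts(self):
        sc = ScenarioConfig(
            n_studies=10, total_size=500,
            generation_mode="stratified_intercept", seed=21,
        )
        d = generate_dataset(sc)
        half = math.sqrt(3.0 * sc.tau0_sq)
        assert np.all(np.abs(d.true_b0) <= half)
        assert len(d.true_b0) == len(d.true_b1) == 10

    def test_every_study_present(self):
        sc = ScenarioConfig(n_studies=15, total_size=500,
                            size_scheme="imbalanced", seed=3)
        d = generate_dataset(sc)
        assert set(np.unique(d.study_id)) == set(range(1, 16))
        assert set(np.unique(d.y)) <= {0, 1}


def test_dataset_roundtrip(tmp_path, tiny_dataset):
    path = str(tmp_path / "data.csv")
    write_dataset(tiny_dataset, path)
    back = read_dataset(path)
    assert np.array_equal(back.y, tiny_dataset.y)
    assert np.array_equal(back.x, tiny_dataset.x)
    np.testing.assert_allclose(back.true_b1, tiny_dataset.true_b1)
    assert back.scenario == tiny_dataset.scenario
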