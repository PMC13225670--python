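import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from grexfine import engine
from grexfine.engine import (
    FitConfig,
    RegionData,
    compute_elbo,
    fit,
    init_state,
    truncated_normal_moments,
    update_covariates_intercept,
    update_dirichlet,
    update_hyperparameters,
    update_latent_liabilities,
    update_pleiotropy,
    update_single_effect,
)
from grexfine.io import GReXMatrix, PhenotypeVector
from grexfine.scoring import pair_pip

from conftest import make_region


class TestTruncatedNormalMoments:
    def test_half_normal_mean(self):
        mean, var, _ = truncated_normal_moments(np.array([0.0]), np.array([1]))
        assert mean[0] == pytest.approx(np.sqrt(2 / np.pi), abs=1e-9)

    def test_case_control_symmetry(self):
        m = np.array([0.7, -1.3, 0.0])
        mean1, var1, _ = truncated_normal_moments(m, np.ones(3, dtype=int))
        mean0, var0, _ = truncated_normal_moments(-m, np.zeros(3, dtype=int))
        assert np.allclose(mean1, -mean0, atol=1e-12)
        assert np.allclose(var1, var0, atol=1e-12)

    @pytest.mark.parametrize("m", [-4.0, -1.0, 0.5, 2.0, 5.5])
    def test_against_quadrature(self, m):
        mean, var, _ = truncated_normal_moments(np.array([m]), np.array([1]))
        Z = norm.cdf(m)
        e1 = integrate.quad(lambda t: t * norm.pdf(t - m), 0, np.inf)[0] / Z
        e2 = integrate.quad(lambda t: t * t * norm.pdf(t - m), 0, np.inf)[0] / Z
        assert mean[0] == pytest.approx(e1, abs=1e-8)
        assert var[0] == pytest.approx(e2 - e1**2, abs=1e-8)

    def test_extreme_predictor_is_stable(self):
        mean, var, _ = truncated_normal_moments(np.array([-40.0, 40.0]), np.array([1, 1]))
        assert np.isfinite(mean).all() and np.isfinite(var).all()
        assert mean[0] > 0 and var[0] > 0


class TestInitState:
    def test_balanced_phenotype_gives_zero_intercept(self):
        region = make_region(n=40, seed=1)
        region.phenotype.values[:] = np.array([0, 1] * 20)
        state = init_state(region, FitConfig(L=2))
        assert state.mu_mean == pytest.approx(0.0, abs=1e-12)

    def test_uniform_selection_rows(self):
        region = make_region(n=30, M=1, K=3, seed=2)
        state = init_state(region, FitConfig(L=2))
        assert np.allclose(state.gamma_prob, 1 / 3)

    def test_single_class_phenotype_errors(self):
        region = make_region(n=20, seed=3)
        region.phenotype.values[:] = 1
        with pytest.raises(ValueError, match="at least one case"):
            init_state(region, FitConfig())


def _prepared_state(region, config, residual):
    """State with z fixed to a chosen residual and all effects zeroed."""
    state = init_state(region, config)
    state.z_mean = residual.astype(float)
    state.z_m = np.zeros_like(state.z_mean)
    state.z_var = np.ones_like(state.z_mean)
    state.mu_mean = 0.0
    return state


class TestSingleEffect:
    def test_p_equals_one_forces_selection(self):
        region = make_region(n=25, M=1, K=1, seed=4)
        config = FitConfig(L=1, include_intercept=False)
        state = _prepared_state(region, config, np.random.default_rng(0).normal(size=25))
        update_single_effect(state, region, 0)
        assert state.gamma_prob[0, 0] == pytest.approx(1.0)

    def test_identical_columns_split_half(self):
        rng = np.random.default_rng(5)
        n = 40
        x = rng.standard_normal(n)
        grex = GReXMatrix(np.column_stack([x, x]), [("g1", "t1"), ("g1", "t2")])
        y = PhenotypeVector((x > 0).astype(int))
        region = RegionData(grex=grex, phenotype=y)
        config = FitConfig(L=1, include_intercept=False)
        state = _prepared_state(region, config, x + rng.normal(0, 0.2, n))
        update_single_effect(state, region, 0)
        assert state.gamma_prob[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_matches_exact_enumeration_oracle(self):
        # p=3, n=12: normalize the exact single-effect marginal likelihoods
        rng = np.random.default_rng(6)
        n, p = 12, 3
        G = rng.standard_normal((n, p))
        from grexfine.io import standardize_columns

        Gs, _ = standardize_columns(G)
        grex = GReXMatrix(Gs, [("g1", "t1"), ("g1", "t2"), ("g1", "t3")])
        grex.standardized = True
        region = RegionData(grex=grex, phenotype=PhenotypeVector((rng.random(n) > 0.5).astype(int)))
        config = FitConfig(L=1, include_intercept=False, sigma2_beta_init=0.8)
        r = rng.normal(size=n)
        state = _prepared_state(region, config, r)
        update_single_effect(state, region, 0)
        logls = np.array(
            [
                multivariate_normal.logpdf(
                    r, mean=np.zeros(n), cov=np.eye(n) + 0.8 * np.outer(Gs[:, j], Gs[:, j])
                )
                for j in range(p)
            ]
        )
        expected = np.exp(logls - logls.max())
        expected /= expected.sum()
        assert np.allclose(state.gamma_prob[0], expected, atol=1e-6)

    def test_rows_stay_normalized(self, small_region, fast_config):
        state = init_state(small_region, fast_config)
        update_latent_liabilities(state, small_region)
        for l in range(fast_config.L):
            update_single_effect(state, small_region, l)
        assert np.allclose(state.gamma_prob.sum(axis=1), 1.0, atol=1e-8)


class TestPleiotropy:
    def test_s_zero_is_noop(self, small_region, fast_config):
        state = init_state(small_region, fast_config)
        before = state.alpha_mean.copy()
        update_pleiotropy(state, small_region)
        assert np.array_equal(state.alpha_mean, before)

    def test_infinite_shrinkage_limit(self):
        region = make_region(n=50, seed=7, s=4)
        state = init_state(region, FitConfig(L=1))
        state.hyper.sigma2_alpha = 1e-12
        update_latent_liabilities(state, region)
        update_pleiotropy(state, region)
        assert np.abs(state.alpha_mean).max() < 1e-8

    def test_orthonormal_closed_form(self):
        # X with X'X = I: alpha_j = (X' r)_j / (1 + 1/sigma2)
        rng = np.random.default_rng(8)
        n, s = 30, 4
        Q, _ = np.linalg.qr(rng.standard_normal((n, s)))
        r = rng.normal(size=n)
        grex = GReXMatrix(rng.standard_normal((n, 2)), [("g1", "t1"), ("g1", "t2")])
        region = RegionData(grex=grex, phenotype=PhenotypeVector((rng.random(n) > 0.5).astype(int)))
        region.genotypes = Q  # bypass standardization to keep orthonormality
        config = FitConfig(L=1, include_intercept=False, sigma2_alpha_init=0.5)
        state = init_state(region, config)
        state.z_mean = r
        state.mu_mean = 0.0
        state.gamma_prob[:] = 1 / 2
        state.mu_post[:] = 0.0
        update_pleiotropy(state, region)
        expected = (Q.T @ r) / (1 + 1 / 0.5)
        assert np.allclose(state.alpha_mean, expected, atol=1e-8)


class TestCovariatesIntercept:
    def test_zero_residual_gives_zero_intercept(self, small_region):
        state = init_state(small_region, FitConfig(L=2))
        state.z_mean = np.zeros(small_region.n)
        update_covariates_intercept(state, small_region)
        assert state.mu_mean == pytest.approx(0.0)
        assert state.mu_var == pytest.approx(1 / small_region.n)

    def test_c_zero_skips_xi(self, small_region):
        state = init_state(small_region, FitConfig(L=2))
        update_covariates_intercept(state, small_region)
        assert state.xi_mean.size == 0

    def test_single_covariate_least_squares(self):
        region = make_region(n=60, seed=9, c=1)
        state = init_state(region, FitConfig(L=1))
        rng = np.random.default_rng(10)
        r = rng.normal(size=60)
        state.z_mean = r
        state.gamma_prob[:] = 1 / region.p
        state.mu_post[:] = 0.0
        update_covariates_intercept(state, region)
        C = region.covariates.values
        expected = float(C[:, 0] @ (r - state.mu_mean)) / float(C[:, 0] @ C[:, 0])
        assert state.xi_mean[0] == pytest.approx(expected, abs=1e-10)

    def test_collinear_covariates_error(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(30)
        from grexfine.io import CovariateMatrix

        region = make_region(n=30, seed=12)
        region.covariates = CovariateMatrix(
            np.column_stack([x, x]), names=["a", "b"], standardized=True
        )
        with pytest.raises(ValueError, match="collinear"):
            init_state(region, FitConfig(L=1))


class TestDirichlet:
    def test_uniform_selection_symmetry(self):
        region = make_region(n=20, M=2, K=3, seed=13)
        state = init_state(region, FitConfig(L=1))
        update_dirichlet(state, region)
        p, K = region.p, region.grex.K
        assert np.allclose(state.delta_gene, 1 + K / p)

    def test_unit_count_concentration(self):
        region = make_region(n=20, M=2, K=2, seed=14)
        state = init_state(region, FitConfig(L=1))
        state.gamma_prob[:] = 0.0
        # column for gene g0, tissue t1
        j = [i for i, pr in enumerate(region.grex.pairs) if pr == ("g0", "t1")][0]
        state.gamma_prob[0, j] = 1.0
        update_dirichlet(state, region)
        g = region.grex.genes.index("g0")
        t = region.grex.tissues.index("t1")
        assert state.delta_gene[g] == pytest.approx(2.0)
        assert state.delta_tissue[g, t] == pytest.approx(2.0)
        assert state.delta_gene.sum() == pytest.approx(region.grex.M + 1)

    def test_matches_bruteforce_sums(self):
        region = make_region(n=20, M=2, K=2, seed=15)
        rng = np.random.default_rng(16)
        state = init_state(region, FitConfig(L=3))
        raw = rng.random((3, region.p))
        state.gamma_prob = raw / raw.sum(axis=1, keepdims=True)
        update_dirichlet(state, region)
        for m in range(region.grex.M):
            total = sum(
                state.gamma_prob[l, j]
                for l in range(3)
                for j in range(region.p)
                if region.grex.gene_index[j] == m
            )
            assert state.delta_gene[m] == pytest.approx(1 + total, abs=1e-12)
            for k in range(region.grex.K):
                tk = sum(
                    state.gamma_prob[l, j]
                    for l in range(3)
                    for j in range(region.p)
                    if region.grex.gene_index[j] == m and region.grex.tissue_index[j] == k
                )
                assert state.delta_tissue[m, k] == pytest.approx(1 + tk, abs=1e-12)


class TestHyperparameters:
    def test_moment_match(self):
        region = make_region(n=20, M=1, K=2, seed=17)
        config = FitConfig(L=2, sigma2_beta_mode="shared")
        state = init_state(region, config)
        state.mu_post[:] = 0.0
        state.s2_post[:] = 0.3
        update_hyperparameters(state, region, config)
        assert state.hyper.sigma2_beta == pytest.approx(0.3)

    def test_floor_engaged(self):
        region = make_region(n=20, M=1, K=2, seed=18)
        config = FitConfig(L=2, sigma2_beta_mode="shared")
        state = init_state(region, config)
        state.mu_post[:] = 0.0
        state.s2_post[:] = 0.0
        update_hyperparameters(state, region, config)
        assert state.hyper.sigma2_beta == pytest.approx(1e-8)

    def test_update_maximizes_elbo_term(self):
        # the sigma2_beta-dependent ELBO piece, scanned on a 1-d grid
        region = make_region(n=20, M=1, K=2, seed=19)
        config = FitConfig(L=2, sigma2_beta_mode="shared")
        state = init_state(region, config)
        rng = np.random.default_rng(20)
        state.mu_post = rng.normal(size=state.mu_post.shape) * 0.5
        state.s2_post = np.full_like(state.s2_post, 0.1)
        second = np.sum(state.gamma_prob * (state.mu_post**2 + state.s2_post), axis=1)
        update_hyperparameters(state, region, config)
        opt = state.hyper.sigma2_beta

        def term(v):
            return -0.5 * float(np.sum(np.log(v) + second / v))

        grid = np.linspace(0.5 * opt, 2.0 * opt, 401)
        assert term(opt) >= max(term(v) for v in grid) - 1e-10
        assert opt == pytest.approx(second.mean())


class TestElboAndFit:
    def test_elbo_nondecreasing_over_seeded_fixtures(self):
        for seed in range(50):
            region = make_region(
                n=40, M=2, K=3, seed=seed, s=6 if seed % 2 else 0, c=2 if seed % 3 == 0 else 0
            )
            _, result = fit(region, FitConfig(L=3, max_iter=25))
            trace = result.elbo_trace
            diffs = np.diff(trace)
            assert (diffs >= -1e-6 * np.abs(trace[:-1])).all(), f"seed {seed}"

    def test_elbo_bounded_by_quadrature_marginal(self):
        # 2 observations, 1 pair, no intercept/pleiotropy, fixed sigma2_beta:
        # log marginal = log int N(b;0,v) prod_i Phi((2y_i-1) g_i b) db
        g = np.array([1.3, -0.4])
        gs = (g - g.mean()) / g.std()
        grex = GReXMatrix(gs[:, None], [("g1", "t1")])
        grex.standardized = True
        region = RegionData(grex=grex, phenotype=PhenotypeVector(np.array([1, 0])))
        config = FitConfig(
            L=1,
            include_intercept=False,
            update_hyperparameters=False,
            sigma2_beta_init=0.7,
            max_iter=100,
        )
        _, result = fit(region, config)
        sign = np.array([1.0, -1.0])

        def integrand(b):
            return norm.pdf(b, 0, np.sqrt(0.7)) * np.prod(norm.cdf(sign * gs * b))

        marg, _ = integrate.quad(integrand, -10, 10)
        assert result.elbo_trace[-1] <= np.log(marg) + 1e-6

    def test_permutation_equivariance(self):
        region = make_region(n=80, M=2, K=2, seed=30, causal_col=1, effect=0.8)
        _, res1 = fit(region, FitConfig(L=2, max_iter=60))
        perm = [2, 0, 3, 1]
        grex2 = GReXMatrix(
            region.grex.values[:, perm], [region.grex.pairs[j] for j in perm]
        )
        grex2.standardized = True
        region2 = RegionData(grex=grex2, phenotype=region.phenotype)
        _, res2 = fit(region2, FitConfig(L=2, max_iter=60))
        key = lambda df: df.sort_values(["gene", "tissue"])["pip"].to_numpy()
        assert np.allclose(key(res1.pair_table), key(res2.pair_table), atol=1e-8)

    def test_label_flip_symmetry(self):
        region = make_region(n=100, M=2, K=2, seed=31, causal_col=0, effect=0.7)
        _, res1 = fit(region, FitConfig(L=2, max_iter=80))
        flipped = RegionData(
            grex=region.grex, phenotype=PhenotypeVector(1 - region.phenotype.values)
        )
        _, res2 = fit(flipped, FitConfig(L=2, max_iter=80))
        assert np.allclose(
            res1.pair_table["pip"].to_numpy(), res2.pair_table["pip"].to_numpy(), atol=1e-6
        )

    def test_null_fixture_rarely_confident(self):
        confident = 0
        for seed in range(20):
            region = make_region(n=500, M=5, K=4, seed=200 + seed)
            state, _ = fit(region, FitConfig(L=3, max_iter=60))
            if pair_pip(state.gamma_prob).max() > 0.95:
                confident += 1
        assert confident <= 2  # no pair PIP > 0.95 in >= 90% of runs

    def test_strong_signal_attains_top_pip(self):
        top_hits = 0
        for seed in range(20):
            region = make_region(
                n=1000, M=5, K=2, seed=300 + seed, causal_col=3, effect=np.sqrt(0.1 / 0.9)
            )
            state, _ = fit(region, FitConfig(L=3, max_iter=60))
            pips = pair_pip(state.gamma_prob)
            if np.argmax(pips) == 3:
                top_hits += 1
        assert top_hits >= 18  # top PIP on the causal pair in >= 90% of runs

    def test_gene_pips_sum_to_one(self, small_region):
        _, result = fit(small_region, FitConfig(L=3, max_iter=40))
        assert result.gene_table["gene_pip"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_nonfinite_predictor_raises(self, small_region):
        state = init_state(small_region, FitConfig(L=2))
        state.mu_mean = np.nan
        with pytest.raises(FloatingPointError, match="non-finite"):
            update_latent_liabilities(state, small_region)
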