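"""State-space model: density oracles, gradient exactness, fit contract,
posterior summaries and horseshoe behaviour."""

import numpy as np
import pytest
from scipy import stats

from eczema_ssm import (
    MCMCConfig,
    ModelSpec,
    SimulationConfig,
    build_model,
    coefficient_summary,
    covariate_contribution,
    diagnostics,
    draw_true_parameters,
    fit,
    latent_transition_density,
    measurement_logdensity,
    predict,
    simulate_dataset,
    variance_decomposition,
)
from conftest import make_fake_posterior


@pytest.fixture(scope="module")
def fitted_tiny(tiny_cohort):
    _, _, ds, _ = tiny_cohort
    spec = ModelSpec(scale=ds.scale)
    mcmc = MCMCConfig(n_chains=2, n_iterations=400, seed=3)
    return ds, spec, mcmc, fit(ds, spec, mcmc)


class TestDensities:
    def test_transition_is_gaussian(self):
        # at the mean with sigma_l = 1 the log density is log phi(0)
        val = latent_transition_density(5.0, 5.0, 1.0, 0.0, np.zeros(2), np.zeros(2), 1.0)
        assert val == pytest.approx(-0.9189385, abs=1e-6)
        # alpha = 1, b = 0: identical to a random-walk step density
        rw = stats.norm.logpdf(7.3, loc=6.1, scale=2.0)
        val = latent_transition_density(7.3, 6.1, 1.0, 0.0, np.zeros(1), np.zeros(1), 2.0)
        assert val == pytest.approx(rw, abs=1e-12)

    def test_covariates_null_when_beta_zero(self):
        for x in (np.zeros(3), np.array([5.0, -2.0, 1.0])):
            assert latent_transition_density(
                4.0, 3.0, 0.5, 1.0, x, np.zeros(3), 1.0
            ) == pytest.approx(
                latent_transition_density(4.0, 3.0, 0.5, 1.0, np.zeros(3), np.zeros(3), 1.0)
            )

    def test_measurement_density(self):
        val = measurement_logdensity(36.0, 36.0, 1.0, 72.0)
        assert np.exp(val) == pytest.approx(0.3989423, abs=1e-6)
        with pytest.raises(ValueError):
            measurement_logdensity(36.0, 36.0, -1.0, 72.0)
        with pytest.raises(ValueError):
            measurement_logdensity(80.0, 36.0, 1.0, 72.0)


class TestJointDensity:
    @pytest.mark.parametrize("with_covariates", [False, True])
    def test_gradient_matches_finite_differences(self, with_covariates):
        cfg = SimulationConfig(n_patients=3, n_biomarkers=2, seed=21,
                               sparsity=1 if with_covariates else 0)
        ds, _ = simulate_dataset(draw_true_parameters(cfg), cfg)
        spec = ModelSpec(scale=ds.scale, include_covariates=with_covariates,
                         n_covariates=ds.n_covariates if with_covariates else 0)
        model = build_model(spec, ds)
        rng = np.random.default_rng(1)
        theta = model.initial_point(rng) + 0.05 * rng.standard_normal(model.dim)
        _, grad = model.logp_and_grad(theta)
        eps = 1e-6
        for i in rng.choice(model.dim, size=min(40, model.dim), replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (model.logp_and_grad(tp)[0] - model.logp_and_grad(tm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=5e-5, abs=1e-6)

    def test_logdensity_equals_term_by_term_sum(self):
        """Difference of joint log densities at two points equals the
        hand-summed prior + measurement terms computed with scipy."""
        cfg = SimulationConfig(n_patients=2, n_biomarkers=2, seed=22)
        ds, _ = simulate_dataset(draw_true_parameters(cfg), cfg)
        ds = ds.subset([0])
        spec = ModelSpec(scale=ds.scale)
        model = build_model(spec, ds)
        rng = np.random.default_rng(5)

        def oracle(theta):
            p = model.unpack(theta)
            mu_a, lsa, mu_b, lsb, lsl, lsm = theta[:6]
            K = 1
            a_raw = theta[6:7]
            b_raw = theta[7:8]
            u0 = theta[8:9]
            z = theta[9 : 9 + 12]
            lp = stats.norm.logpdf(mu_a, 1.0, 1.0)
            lp += stats.halfnorm.logpdf(p["sigma_alpha"], scale=1.0) + lsa
            lp += stats.norm.logpdf(mu_b, 0.0, 7.2)
            lp += stats.halfnorm.logpdf(p["sigma_b"], scale=3.6) + lsb
            lp += stats.halfnorm.logpdf(p["sigma_l"], scale=7.2) + lsl
            lp += stats.halfnorm.logpdf(p["sigma_m"], scale=7.2) + lsm
            lp += stats.norm.logpdf(a_raw).sum() + stats.norm.logpdf(b_raw).sum()
            lp += stats.norm.logpdf(z).sum()
            sig = 1 / (1 + np.exp(-u0))
            lp += np.log(1 / 72.0) + np.log(72.0 * sig * (1 - sig)).sum()
            S = p["latent"][0]
            sm = p["sigma_m"]
            for t in np.flatnonzero(ds.grid.observed_mask[0]):
                a, b = (0 - S[t]) / sm, (72.0 - S[t]) / sm
                lp += stats.truncnorm.logpdf(ds.grid.values[0, t], a, b,
                                             loc=S[t], scale=sm)
            return float(lp)

        t1 = model.initial_point(rng) + 0.1 * rng.standard_normal(model.dim)
        t2 = model.initial_point(rng) + 0.1 * rng.standard_normal(model.dim)
        ours = model.logp_and_grad(t1)[0] - model.logp_and_grad(t2)[0]
        theirs = oracle(t1) - oracle(t2)
        assert ours == pytest.approx(theirs, rel=1e-8, abs=1e-7)

    def test_covariate_free_spec_has_no_beta(self, fitted_tiny):
        _, _, _, post = fitted_tiny
        assert "beta" not in post.params


class TestFitContract:
    def test_retained_draws_and_supports(self, fitted_tiny):
        ds, spec, mcmc, post = fitted_tiny
        assert post.n_draws == mcmc.n_chains * mcmc.n_kept == 2 * 200
        assert (post.stacked("sigma_l") > 0).all()
        assert (post.stacked("sigma_m") > 0).all()
        alpha = post.stacked("alpha")
        assert ((alpha > 0) & (alpha < 1)).all()
        assert post.stacked("latent").shape == (400, ds.n_patients, 13)

    def test_default_config_draw_count(self):
        mcmc = MCMCConfig()
        assert mcmc.n_chains * mcmc.n_kept == 4000

    def test_predict_support_and_horizon(self, fitted_tiny):
        ds, _, _, post = fitted_tiny
        pred = predict(post, 0, horizon=1, from_time=6)
        assert 0.0 <= pred.mean() <= 72.0
        draws = pred.sample(500, np.random.default_rng(0))
        assert draws.min() >= 0 and draws.max() <= 72
        with pytest.raises(ValueError):
            pred.logpdf(73.0)  # no predictive mass outside [0, M]
        with pytest.raises(ValueError):
            predict(post, 0, horizon=1)  # last visit is t=12, the grid end


class TestSummaries:
    def test_variance_decomposition_symmetry(self):
        post = make_fake_posterior(sigma_l=2.0, sigma_m=2.0)
        frac, (lo, hi) = variance_decomposition(post)
        assert frac == pytest.approx(0.5, abs=1e-6)
        post = make_fake_posterior(sigma_l=1e-9, sigma_m=3.0)
        frac, _ = variance_decomposition(post)
        assert frac == pytest.approx(1.0, abs=1e-6)

    def test_contribution_dot_product_oracle(self):
        post = make_fake_posterior(n_cov=2, seed=4)
        tab = covariate_contribution(post)
        beta = post.stacked("beta")
        X = post.dataset.covariate_matrix
        for i in range(post.dataset.n_patients):
            per_draw = np.array([X[i] @ b for b in beta])  # explicit dot products
            assert tab.loc[i, "mean"] == pytest.approx(per_draw.mean())
            assert tab.loc[i, "q5"] == pytest.approx(np.quantile(per_draw, 0.05))

    def test_coefficient_summary_errors_without_covariates(self):
        with pytest.raises(ValueError):
            coefficient_summary(make_fake_posterior(n_cov=0))
        tab = coefficient_summary(make_fake_posterior(n_cov=3))
        assert list(tab.columns) == ["covariate", "mean", "q5", "q95"]
        assert len(tab) == 3


class TestDiagnostics:
    def test_white_noise_chains_converged(self):
        post = make_fake_posterior(n_chains=4, n_draws=400, seed=8)
        rep = diagnostics(post, quiet=True)
        assert (rep["rhat"] < 1.02).all()
        assert (rep["ess"] <= post.n_draws).all()

    def test_disjoint_chains_flagged(self):
        post = make_fake_posterior(n_chains=2, n_draws=200, seed=9)
        post.params["sigma_l"] = np.vstack(
            [np.random.default_rng(0).normal(1.0, 0.01, 200),
             np.random.default_rng(1).normal(5.0, 0.01, 200)]
        )
        rep = diagnostics(post, quiet=True)
        row = rep[rep["parameter"] == "sigma_l"].iloc[0]
        assert row["rhat"] > 1.5 and row["flag"] == "warn"

    def test_single_chain_rejected(self):
        post = make_fake_posterior(n_chains=2)
        for k in post.params:
            post.params[k] = post.params[k][:1]
        with pytest.raises(ValueError):
            diagnostics(post)


class TestHorseshoe:
    def test_signal_preserved_and_noise_shrunk(self):
        """One strong coefficient among eight: its 90% CI excludes zero
        while the null coefficients shrink toward zero."""
        cfg = SimulationConfig(n_patients=30, n_biomarkers=4, seed=31,
                               sparsity=1, beta_magnitude=3.0)
        tp = draw_true_parameters(cfg)
        ds, _ = simulate_dataset(tp, cfg)
        spec = ModelSpec(scale=ds.scale, include_covariates=True,
                         n_covariates=ds.n_covariates)
        post = fit(ds, spec, MCMCConfig(n_chains=2, n_iterations=700, seed=5))
        tab = coefficient_summary(post)
        j = int(np.flatnonzero(tp.beta)[0])
        assert tab.loc[j, "q5"] * tab.loc[j, "q95"] > 0  # CI excludes 0
        null_idx = [i for i in range(len(tab)) if i != j]
        assert tab.loc[null_idx, "mean"].abs().mean() < 0.5
        # row permutation follows covariate permutation
        assert list(tab["covariate"]) == ds.covariate_names
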