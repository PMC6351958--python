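import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crashspat import (
    ConfigError,
    CrashspatError,
    McmcConfig,
    ModelSpec,
    PriorConfig,
    build_chain_weights,
    gibbs_update_tau_c,
    gibbs_update_tau_h,
    icar_log_density,
    log_poisson_likelihood,
    run_mcmc,
    validate_segments,
)
from crashspat.model_mcmc import (
    MetropolisWithinGibbs,
    tau_c_posterior_params,
    tau_h_posterior_params,
)


def _flat_table(n, counts, aadt=10000.0):
    df = pd.DataFrame(
        {
            "segment_id": np.arange(1, n + 1),
            "length": 1.0,
            "curvature": 0.0,
            "grade": 0.0,
            "bridge": 0,
            "ramp": 0,
            "aadt": aadt,
            "crash_count": counts,
        }
    )
    return validate_segments(df)


class TestPoissonLikelihood:
    def test_zero_count_unit_rate(self):
        assert log_poisson_likelihood([0], [0.0]) == pytest.approx(-1.0)

    def test_closed_form_small_case(self):
        # Y=2, lambda=2: 2 log 2 - 2 - log 2! = log 2 - 2
        assert log_poisson_likelihood([2], [np.log(2.0)]) == pytest.approx(
            np.log(2.0) - 2.0
        )

    def test_additivity_over_segments(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, 10)
        eta = rng.normal(1.0, 0.3, 10)
        total = log_poisson_likelihood(y, eta)
        parts = sum(log_poisson_likelihood([yi], [ei]) for yi, ei in zip(y, eta))
        assert total == pytest.approx(parts)

    def test_invalid_counts_rejected(self):
        with pytest.raises(CrashspatError):
            log_poisson_likelihood([-1], [0.0])
        with pytest.raises(CrashspatError):
            log_poisson_likelihood([1.5], [0.0])


class TestIcarLogDensity:
    def test_constant_field_has_zero_quadratic_term(self):
        w = build_chain_weights(6)
        phi = np.full(6, 2.7)
        val = icar_log_density(phi, w, tau_c=3.0)
        assert val == pytest.approx(0.5 * 5 * np.log(3.0))

    def test_shift_invariance(self):
        w = build_chain_weights(9)
        rng = np.random.default_rng(1)
        phi = rng.normal(size=9)
        base = icar_log_density(phi, w, 0.7)
        for c in (-5.0, 0.3, 12.0):
            assert abs(icar_log_density(phi + c, w, 0.7) - base) < 1e-10

    def test_hand_value_three_chain(self):
        w = build_chain_weights(3)
        # quadratic term: (0-1)^2 + (1-0)^2 = 2; tau_c/2 * 2 = 2
        val = icar_log_density([0.0, 1.0, 0.0], w, tau_c=2.0)
        assert val == pytest.approx(np.log(2.0) - 2.0)

    def test_nonpositive_tau_rejected(self):
        w = build_chain_weights(3)
        with pytest.raises(CrashspatError):
            icar_log_density([0.0, 1.0, 0.0], w, 0.0)


class TestPrecisionConditionals:
    def test_tau_h_conjugacy_algebra(self):
        shape, rate = tau_h_posterior_params([1.0, -1.0], PriorConfig())
        assert (shape, rate) == (pytest.approx(1.001), pytest.approx(1.001))

    def test_tau_h_zero_field(self):
        shape, rate = tau_h_posterior_params(np.zeros(10), PriorConfig())
        assert (shape, rate) == (pytest.approx(5.001), pytest.approx(0.001))

    def test_tau_c_hand_quadratic(self):
        w = build_chain_weights(3)
        shape, rate = tau_c_posterior_params([0.0, 1.0, 0.0], w, PriorConfig())
        assert shape == pytest.approx(0.001 + 1.0)  # (n-1)/2 = 1
        assert rate == pytest.approx(0.001 + 1.0)

    def test_tau_c_constant_field_keeps_prior_rate(self):
        w = build_chain_weights(8)
        shape, rate = tau_c_posterior_params(np.full(8, 1.3), w, PriorConfig())
        assert shape == pytest.approx(0.001 + 3.5)
        assert rate == pytest.approx(0.001)

    def test_tau_c_rejects_disconnected_graph(self):
        from crashspat.adjacency import WeightMatrix

        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(CrashspatError, match="disconnected"):
            tau_c_posterior_params(np.zeros(4), WeightMatrix(4, w), PriorConfig())

    def test_gamma_mean_of_draws(self):
        """theta = 0-vector, n=10: mean of gamma(5.001, 0.001) draws ~ 5001."""
        rng = np.random.default_rng(2)
        draws = np.array(
            [gibbs_update_tau_h(np.zeros(10), PriorConfig(), rng) for _ in range(20000)]
        )
        assert draws.mean() == pytest.approx(5.001 / 0.001, rel=0.02)


class TestSamplerMechanics:
    def test_same_seed_is_bit_identical(self, small_table):
        spec = ModelSpec("hybrid", covariates=("curvature",),
                         spillover_covariates=())
        cfg = McmcConfig(iterations=400, burn_in=200, thin=2, seed=42)
        a = run_mcmc(small_table, None, spec, PriorConfig(), cfg)
        b = run_mcmc(small_table, None, spec, PriorConfig(), cfg)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_phi_draws_are_centered(self, small_table):
        spec = ModelSpec("car", covariates=())
        cfg = McmcConfig(iterations=500, burn_in=100, thin=1, seed=3)
        s = run_mcmc(small_table, None, spec, PriorConfig(), cfg)
        assert np.all(np.abs(s.phi.mean(axis=1)) < 1e-10)

    def test_car_ignores_spillover_columns(self, small_table):
        from crashspat import build_spillover

        sp = build_spillover(small_table)
        spec = ModelSpec("car", covariates=("curvature",))
        cfg = McmcConfig(iterations=300, burn_in=100, thin=1, seed=9)
        with_sp = run_mcmc(small_table, sp, spec, PriorConfig(), cfg)
        without = run_mcmc(small_table, None, spec, PriorConfig(), cfg)
        np.testing.assert_array_equal(with_sp.alpha, without.alpha)
        np.testing.assert_array_equal(with_sp.slopes, without.slopes)

    def test_missing_covariate_column_is_config_error(self, small_table):
        spec = ModelSpec("car", covariates=("nonexistent",))
        with pytest.raises(ConfigError, match="nonexistent"):
            run_mcmc(small_table, None, spec, PriorConfig(),
                     McmcConfig(iterations=10, burn_in=1, thin=1))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            McmcConfig(iterations=100, burn_in=100)
        with pytest.raises(ConfigError):
            McmcConfig(initial_scale=0.0)
        with pytest.raises(ConfigError):
            ModelSpec("car", spillover_covariates=("grade_adj",))
        with pytest.raises(ConfigError):
            ModelSpec("banana")

    def test_acceptance_rates_near_target(self):
        rng = np.random.default_rng(4)
        n = 60
        table = _flat_table(n, rng.poisson(5.0, n),
                            aadt=rng.uniform(5000, 40000, n))
        spec = ModelSpec("hybrid", covariates=())
        cfg = McmcConfig(iterations=4000, burn_in=2000, thin=2, seed=5,
                         adapt_target=0.44)
        s = run_mcmc(table, None, spec, PriorConfig(), cfg)
        for name, rate in s.acceptance.items():
            assert abs(rate - 0.44) < 0.15, (name, rate)


class TestSamplerPosteriors:
    def test_intercept_only_recovery(self):
        """Counts simulated at lambda=5: posterior of exp(alpha) covers 5."""
        rng = np.random.default_rng(6)
        n = 120
        table = _flat_table(n, rng.poisson(5.0, n))
        spec = ModelSpec("spillover", covariates=(), exposure=None)
        cfg = McmcConfig(iterations=6000, burn_in=2000, thin=4, seed=7)
        s = run_mcmc(table, None, spec, PriorConfig(), cfg)
        lam = np.exp(s.alpha)
        lo, hi = np.quantile(lam, [0.025, 0.975])
        assert lo < 5.0 < hi
        assert lam.mean() == pytest.approx(5.0, rel=0.15)

    def test_exposure_shift_moves_intercept_only(self):
        """Adding c to log-exposure shifts alpha by -beta0*c, draw by draw."""
        rng = np.random.default_rng(8)
        n = 50
        table = _flat_table(n, rng.poisson(4.0, n),
                            aadt=rng.uniform(5000, 40000, n))
        shifted = table.copy()
        c = 2.0
        shifted["log_dvkt"] = shifted["log_dvkt"] + c
        spec = ModelSpec("spillover", covariates=())
        # near-flat coefficient prior so the shifted and unshifted chains
        # take identical accept/reject paths
        priors = PriorConfig(coef_prior_variance=1e12)
        cfg = McmcConfig(iterations=2000, burn_in=1000, thin=2, seed=21)
        base = run_mcmc(table, None, spec, priors, cfg)
        moved = run_mcmc(shifted, None, spec, priors, cfg)
        np.testing.assert_allclose(moved.slopes, base.slopes, atol=1e-9)
        np.testing.assert_allclose(
            moved.alpha, base.alpha - c * base.slopes[:, 0], atol=1e-9
        )

    def test_theta_shrinks_as_precision_grows(self):
        """Prior domination: larger tau_h pulls the theta field toward 0."""
        rng = np.random.default_rng(9)
        n = 40
        y = rng.poisson(5.0, n)
        table = _flat_table(n, y)
        spec = ModelSpec("spillover", covariates=(), exposure=None)
        means = []
        for tau in (0.5, 10.0, 1000.0):
            s = MetropolisWithinGibbs(
                y, np.zeros((n, 0)), (), spec, PriorConfig(),
                McmcConfig(iterations=100, burn_in=50, thin=1, seed=11), None,
            )
            s.tau_h = tau
            for _ in range(400):
                s.update_site_effects("theta")
            means.append(np.abs(s.theta).mean())
        assert means[0] > means[1] > means[2]

    def test_flat_data_gives_null_spatial_field(self):
        """All counts equal, no covariates: posterior mean phi ~ 0 by symmetry."""
        n = 12
        table = _flat_table(n, np.full(n, 3))
        spec = ModelSpec("car", covariates=(), exposure=None)
        cfg = McmcConfig(iterations=6000, burn_in=2000, thin=2, seed=13)
        s = run_mcmc(table, None, spec, PriorConfig(), cfg)
        assert np.all(np.abs(s.phi.mean(axis=0)) < 0.15)

    def test_spatial_signal_assigns_variance_to_phi(self):
        """Strong spatial field, no heterogeneity: sigma_c outweighs sigma_h."""
        from crashspat import SimulationScenario, simulate_dataset

        wins = 0
        for rep in range(3):
            scn = SimulationScenario(
                n=100, seed=100 + rep, variant="car",
                true_params={"alpha": -8.8, "beta0": 0.886, "beta": {},
                             "beta_adj": {}, "sigma_h": 0.0, "sigma_c": 0.25},
            )
            table, _, _ = simulate_dataset(scn)
            spec = ModelSpec("hybrid", covariates=())
            cfg = McmcConfig(iterations=4000, burn_in=2000, thin=2,
                             seed=200 + rep)
            s = run_mcmc(table, None, spec, PriorConfig(), cfg)
            if (1.0 / s.tau_c).mean() > (1.0 / s.tau_h).mean():
                wins += 1
        assert wins >= 2
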