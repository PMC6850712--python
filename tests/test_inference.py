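"""Gibbs sampler correctness, posterior functionals and diagnostics."""

import numpy as np
import pytest

from mbhv import (
    ConfigurationError,
    ConvergenceWarning,
    DiagnosticError,
    FitConfig,
    PosteriorEnsemble,
    SimulationScenario,
    center,
    check_convergence,
    fit_empirical,
    fit_structured,
    gelman_rubin,
    pooled_mean,
    posterior_summary,
    raw_covariance,
    simulate_grouped_dataset,
)
from mbhv.inference import _draw_wishart


def _simulated(between_var, seed, n_dims=3, n_groups=4, n_per_group=10, **kw):
    scenario = SimulationScenario(
        n_dims=n_dims,
        n_groups=n_groups,
        n_per_group=n_per_group,
        between_var=between_var,
        seed=seed,
        **kw,
    )
    return scenario, simulate_grouped_dataset(scenario, 0)


class TestFitConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_iterations": 1_000, "n_burnin": 1_000},
            {"n_iterations": 500, "n_burnin": 0, "thin": 10},  # < 100 retained
            {"epsilon": -1.0},
            {"n_chains": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            FitConfig(**kwargs)

    def test_retained_draws(self):
        assert FitConfig(10_000, 5_000, 2, 10).n_retained == 500


class TestSampler:
    def test_seed_determinism(self, centered_data, fast_config):
        centered, _ = centered_data
        a = fit_structured(centered, fast_config)
        b = fit_structured(centered, fast_config)
        np.testing.assert_array_equal(a.group_means, b.group_means)
        np.testing.assert_array_equal(a.covariances, b.covariances)

    def test_all_covariance_draws_are_spd(self, fitted_ensemble):
        for cov in fitted_ensemble.stacked_covariances():
            np.linalg.cholesky(cov)  # raises if not SPD

    def test_recovers_covariance_without_group_structure(self, fast_config):
        # No between-group spread: Sigma should converge on the raw-data
        # covariance, which itself converges on the generating matrix.
        scenario, data = _simulated(0.0, seed=21, n_groups=4, n_per_group=125)
        centered, _ = center(data)
        ens = fit_structured(centered, fast_config)
        post_mean = posterior_summary(ens).mean_covariance
        np.testing.assert_allclose(
            post_mean, scenario.within_cov, rtol=0.10, atol=0.05
        )

    def test_structured_beats_pooled_covariance_under_group_shifts(self, fast_config):
        # With sigma2_b = 2 the pooled covariance is inflated; the
        # within-group Sigma estimate should be closer to the truth
        # (Frobenius norm) in nearly all replicates.
        wins = 0
        n_reps = 50
        scenario = SimulationScenario(between_var=2.0, seed=77, n_reps=n_reps)
        for rep in range(n_reps):
            data = simulate_grouped_dataset(scenario, rep)
            centered, _ = center(data)
            cfg = FitConfig(2_000, 1_000, 2, 5, seed=1_000 + rep)
            post = posterior_summary(fit_structured(centered, cfg)).mean_covariance
            err_post = np.linalg.norm(post - scenario.within_cov)
            err_raw = np.linalg.norm(raw_covariance(centered) - scenario.within_cov)
            wins += err_post < err_raw
        assert wins >= 0.9 * n_reps

    def test_empirical_fit_tracks_raw_covariance_iid(self, fast_config):
        scenario, data = _simulated(0.0, seed=31, n_groups=4, n_per_group=125)
        centered, _ = center(data)
        ens = fit_empirical(centered, fast_config)
        post_mean = posterior_summary(ens).mean_covariance
        np.testing.assert_allclose(post_mean, raw_covariance(centered), rtol=0.10)

    def test_empirical_fit_absorbs_between_group_variance(self, fast_config):
        # Law of total variance: pooled variance tends to diag(Sigma) + sigma2_b.
        scenario, data = _simulated(
            2.0, seed=41, n_groups=10, n_per_group=50
        )
        centered, _ = center(data)
        ens = fit_empirical(centered, fast_config)
        post_diag = np.diag(posterior_summary(ens).mean_covariance)
        assert np.all(post_diag > np.diag(scenario.within_cov))

    def test_tiny_epsilon_shrinks_group_means_to_zero(self, centered_data):
        centered, _ = centered_data
        cfg = FitConfig(3_000, 1_000, 2, 10, epsilon=1e-8, seed=3)
        ens = fit_structured(centered, cfg)
        assert np.max(np.abs(ens.group_means)) < 1e-3
        # ... and Sigma approaches the empirical fit's Sigma.
        emp = fit_empirical(centered, cfg)
        np.testing.assert_allclose(
            posterior_summary(ens).mean_covariance,
            posterior_summary(emp).mean_covariance,
            rtol=0.15,
            atol=0.05,
        )

    def test_single_group_structured_equals_empirical(self, fast_config):
        scenario, data = _simulated(0.0, seed=51, n_groups=1, n_per_group=30)
        centered, _ = center(data)
        a = fit_structured(centered, fast_config)
        b = fit_empirical(centered, fast_config)
        np.testing.assert_array_equal(a.group_means, b.group_means)
        np.testing.assert_array_equal(a.covariances, b.covariances)

    def test_uncentered_data_warns(self, grouped_data, fast_config):
        with pytest.warns(UserWarning, match="centered"):
            fit_structured(grouped_data, fast_config)

    def test_prior_rate_convention_is_weak(self, fast_config):
        # Whether the Wishart prior rate is Sigma_R or its inverse barely
        # moves the posterior at moderate N: report the sensitivity.
        from mbhv.geometry import posterior_mean_volume

        scenario, data = _simulated(0.0, seed=61, n_groups=4, n_per_group=50)
        centered, _ = center(data)
        default = fit_structured(centered, fast_config)
        flipped = fit_structured(
            centered, fast_config, rate_matrix=np.linalg.inv(raw_covariance(centered))
        )
        v0 = posterior_mean_volume(default)
        v1 = posterior_mean_volume(flipped)
        assert abs(v1 - v0) / v0 < 0.10

    def test_wishart_conditional_moments(self):
        # Bartlett sampler: mean of Wishart(df, rate^{-1}) is df * rate^{-1}.
        rng = np.random.default_rng(8)
        rate = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.5]])
        df = 30.0
        draws = _draw_wishart(rng, df, np.broadcast_to(rate, (4_000, 3, 3)).copy())
        target = df * np.linalg.inv(rate)
        np.testing.assert_allclose(draws.mean(axis=0), target, rtol=0.05, atol=0.05)


class TestPooledMean:
    def test_average_over_groups(self):
        means = np.array([[[[1.0, 0.0, 0.0], [3.0, 2.0, -2.0]]]])  # (1,1,2,3)
        ens = _toy_ensemble(group_means=means)
        np.testing.assert_allclose(pooled_mean(ens)[0, 0], [2.0, 1.0, -1.0])

    def test_identity_for_single_group(self):
        means = np.array([[[[1.0, 2.0, 3.0]]]])
        ens = _toy_ensemble(group_means=means, group_names=("pooled",))
        np.testing.assert_allclose(pooled_mean(ens)[0, 0], [1.0, 2.0, 3.0])


def _toy_ensemble(group_means, covariances=None, group_names=None, n_chains=None):
    """Assemble a PosteriorEnsemble directly (synthetic draws, not a fit)."""
    group_means = np.asarray(group_means, dtype=float)
    c, d, k, j = group_means.shape
    if covariances is None:
        covariances = np.broadcast_to(np.eye(j), (c, d, j, j)).copy()
    if group_names is None:
        group_names = tuple(f"g{i}" for i in range(k))
    return PosteriorEnsemble(
        group_means=group_means,
        covariances=np.asarray(covariances, dtype=float),
        model_kind="structured",
        config=FitConfig(2_000, 1_000, max(c, 1), 10),
        variable_names=tuple(f"x{i}" for i in range(j)),
        group_names=group_names,
    )


class TestGelmanRubin:
    def test_identical_chains_give_rhat_at_most_one(self):
        rng = np.random.default_rng(2)
        one_chain = rng.normal(size=(1, 400, 2, 3))
        ens = _toy_ensemble(np.concatenate([one_chain, one_chain], axis=0))
        assert (gelman_rubin(ens) <= 1.0 + 1e-12).all()

    def test_iid_chains_converged(self):
        rng = np.random.default_rng(3)
        ens = _toy_ensemble(rng.normal(size=(3, 1_000, 2, 3)))
        assert (gelman_rubin(ens) < 1.1).all()

    def test_divergent_chains_flagged_and_match_formula(self):
        rng = np.random.default_rng(4)
        chains = rng.normal(size=(2, 500, 1, 1))
        chains[1] += 10.0  # second chain centered at 10
        ens = _toy_ensemble(chains)
        rhat = gelman_rubin(ens)
        mu_param = rhat.filter(like="mu").iloc[0]
        assert mu_param > 5.0
        # Independent hand computation of the classic statistic.
        trace = chains[:, :, 0, 0]
        n = trace.shape[1]
        w = trace.var(axis=1, ddof=1).mean()
        b_over_n = trace.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        np.testing.assert_allclose(mu_param, expected, rtol=1e-12)

    def test_agrees_with_arviz_on_stationary_chains(self, fitted_ensemble):
        az = pytest.importorskip("arviz")
        rhat = gelman_rubin(fitted_ensemble)
        trace = fitted_ensemble.covariances[:, :, 0, 0]  # (chains, draws)
        ref = float(az.rhat(trace))
        ours = rhat[
            f"Sigma[{fitted_ensemble.variable_names[0]},{fitted_ensemble.variable_names[0]}]"
        ]
        assert abs(ours - ref) < 0.05

    def test_single_chain_is_diagnostic_error(self):
        ens = _toy_ensemble(np.zeros((1, 200, 1, 2)))
        with pytest.raises(DiagnosticError, match="2 chains"):
            gelman_rubin(ens)

    def test_check_convergence_warns_on_divergent_chains(self):
        chains = np.zeros((2, 200, 1, 1))
        chains[0] = np.random.default_rng(5).normal(size=(200, 1, 1))
        chains[1] = chains[0] + 10.0
        ens = _toy_ensemble(chains)
        with pytest.warns(ConvergenceWarning, match="R-hat"):
            offenders = check_convergence(ens)
        assert len(offenders) >= 1


class TestPosteriorSummary:
    def test_identical_draws_zero_width_intervals(self):
        means = np.tile(np.array([[1.0, 2.0, 3.0]]), (2, 150, 1)).reshape(2, 150, 1, 3)
        ens = _toy_ensemble(means)
        table = posterior_summary(ens).table
        mu_rows = table[table.parameter.str.startswith("mu")]
        np.testing.assert_allclose(mu_rows["q97.5"] - mu_rows["q2.5"], 0.0, atol=1e-12)

    def test_mean_covariance_is_elementwise_average(self, fitted_ensemble):
        summary = posterior_summary(fitted_ensemble)
        np.testing.assert_allclose(
            summary.mean_covariance,
            fitted_ensemble.stacked_covariances().mean(axis=0),
            rtol=1e-12,
        )

    def test_interval_coverage_of_generating_covariance(self):
        # sigma2_b = 0 replicates: nominal 95% intervals should cover the
        # generating covariance elements in >= 90% of replicates.
        n_reps = 50
        scenario = SimulationScenario(between_var=0.0, seed=99, n_reps=n_reps)
        j = scenario.n_dims
        idx = [(a, b) for a in range(j) for b in range(a, j)]
        covered = np.zeros((n_reps, len(idx)))
        for rep in range(n_reps):
            data = simulate_grouped_dataset(scenario, rep)
            centered, _ = center(data)
            cfg = FitConfig(2_000, 1_000, 2, 5, seed=500 + rep)
            ens = fit_structured(centered, cfg)
            covs = ens.stacked_covariances()
            for e, (a, b) in enumerate(idx):
                lo, hi = np.quantile(covs[:, a, b], [0.025, 0.975])
                covered[rep, e] = lo <= scenario.within_cov[a, b] <= hi
        assert np.all(covered.mean(axis=0) >= 0.90)


class TestPersistence:
    def test_npz_round_trip(self, fitted_ensemble, tmp_path):
        path = tmp_path / "ensemble.npz"
        fitted_ensemble.save(path)
        loaded = PosteriorEnsemble.load(path)
        np.testing.assert_array_equal(loaded.group_means, fitted_ensemble.group_means)
        np.testing.assert_array_equal(loaded.covariances, fitted_ensemble.covariances)
        assert loaded.model_kind == fitted_ensemble.model_kind
        assert loaded.config == fitted_ensemble.config
        assert loaded.variable_names == fitted_ensemble.variable_names
        np.testing.assert_array_equal(
            loaded.centering.offsets, fitted_ensemble.centering.offsets
        )
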