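"""Bayesian mixing model: sampler correctness, oracles, propagation."""

import numpy as np
import pytest

from isomix import (
    ChainConfig,
    IsotopeMixingModel,
    MixtureObservations,
    SourceProfile,
    analytic_fractions_when_determined,
    fit_mixing_model,
    propagate_across_replicates,
    summarize_posterior,
)
from isomix.mixing import PosteriorFractions, _stick_breaking

pytestmark = pytest.mark.filterwarnings("ignore:split-chain")


def _posterior_from_draws(draws, names=None):
    draws = np.asarray(draws, float)
    names = tuple(names or (f"S{i+1}" for i in range(draws.shape[1])))
    return PosteriorFractions(
        draws=draws,
        source_names=names,
        mean=draws.mean(axis=0),
        sd=draws.std(axis=0, ddof=1) if len(draws) > 1 else np.zeros(draws.shape[1]),
        ci95=np.quantile(draws, [0.025, 0.975], axis=0).T,
    )


class TestStickBreaking:
    def test_zero_maps_to_uniform(self):
        F, _ = _stick_breaking(np.zeros(3))
        assert F == pytest.approx(np.full(4, 0.25))

    def test_image_is_simplex(self, rng):
        for _ in range(100):
            F, _ = _stick_breaking(rng.normal(0, 3, size=3))
            assert np.all(F >= 0)
            assert F.sum() == pytest.approx(1.0, abs=1e-12)

    def test_jacobian_preserves_flat_dirichlet(self):
        """Quadrature check: integrating exp(log|J|) over the unconstrained
        plane must reproduce the flat-Dirichlet moments E[F] = 1/3 and
        E[F²] = 1/6 exactly (the Jacobian is the density pullback)."""
        grid = np.linspace(-16.0, 16.0, 201)
        du = grid[1] - grid[0]
        total = np.zeros(1)
        mom1 = np.zeros(3)
        mom2 = np.zeros(3)
        for u1 in grid:
            for u2 in grid:
                F, lj = _stick_breaking(np.array([u1, u2]))
                w = np.exp(lj)
                total += w
                mom1 += w * F
                mom2 += w * F**2
        # flat Dirichlet on the 2-simplex has area 1/2 in (F1, F2) coords:
        # normalise by the integral itself and compare moments
        assert mom1 / total == pytest.approx(np.full(3, 1 / 3), abs=1e-3)
        assert mom2 / total == pytest.approx(np.full(3, 1 / 6), abs=1e-3)
        # the pullback integrates to the area of the projected simplex, 1/2
        assert total[0] * du * du == pytest.approx(0.5, rel=1e-3)


class TestDeterminedCase:
    def test_two_source_linear_solve(self):
        res = analytic_fractions_when_determined([-27.0], np.array([[-20.0], [-30.0]]))
        assert res.fractions == pytest.approx([0.3, 0.7])
        assert res.feasible

    def test_hull_vertex_gives_indicator(self):
        mu = np.array([[-20.0, -18.0], [-30.0, -29.0], [-25.0, -35.0]])
        res = analytic_fractions_when_determined(mu[1], mu)
        assert res.fractions == pytest.approx([0.0, 1.0, 0.0], abs=1e-9)

    def test_outside_hull_flagged_infeasible(self):
        res = analytic_fractions_when_determined([-40.0], np.array([[-20.0], [-30.0]]))
        assert not res.feasible
        assert res.fractions.min() < 0
        assert res.fractions.sum() == pytest.approx(1.0)

    def test_singular_system_names_collinear_sources(self):
        mu = np.array([[-25.0], [-25.0], [-30.0]])
        with pytest.raises(np.linalg.LinAlgError, match="S1.*S2"):
            analytic_fractions_when_determined([-27.0, -26.0], mu.repeat(2, axis=1))

    def test_non_square_system_rejected(self):
        with pytest.raises(ValueError, match="n_sources"):
            analytic_fractions_when_determined([-27.0], np.array([[-20.0], [-25.0], [-30.0]]))

    def test_posterior_matches_analytic_solution(self):
        model = IsotopeMixingModel(
            source_means=[[-20.0], [-30.0]],
            source_sds=[[0.01], [0.01]],
            n_retained=10_000,
            n_burnin=5_000,
            random_state=3,
        ).fit(np.full((5, 1), -27.0))
        assert model.mean_ == pytest.approx([0.3, 0.7], abs=0.02)


class TestSampler:
    def test_draws_live_on_simplex(self, four_sources, rng):
        obs = MixtureObservations(
            "env", {"formic": rng.normal(-24, 1, 5), "acetic": rng.normal(-26, 1, 5)}
        )
        post = fit_mixing_model(
            obs, four_sources, chain=ChainConfig(n_retained=2000, n_burnin=1000, seed=5)
        )
        assert np.all(post.draws >= 0)
        assert np.allclose(post.draws.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_seed_identical_draws(self, four_sources, rng):
        obs = MixtureObservations(
            "env", {"formic": rng.normal(-24, 1, 4), "acetic": rng.normal(-26, 1, 4)}
        )
        chain = ChainConfig(n_retained=800, n_burnin=400, seed=99)
        p1 = fit_mixing_model(obs, four_sources, chain=chain)
        p2 = fit_mixing_model(obs, four_sources, chain=chain)
        np.testing.assert_array_equal(p1.draws, p2.draws)

    def test_flat_likelihood_recovers_dirichlet_prior(self):
        """Identical sources make the likelihood flat in F, so the posterior
        mean must return the Dirichlet(1,…,1) prior mean 1/K."""
        same = [
            SourceProfile(f"s{i}", {"acetic": -25.0}, {"acetic": 1.0})
            for i in range(3)
        ]
        obs = MixtureObservations("env", {"acetic": [-25.3, -24.8, -25.1]})
        post = fit_mixing_model(
            obs, same, chain=ChainConfig(n_retained=8000, n_burnin=4000, seed=17)
        )
        assert post.mean == pytest.approx(np.full(3, 1 / 3), abs=0.04)

    def test_source_permutation_permutes_summaries(self, four_sources, rng):
        obs = MixtureObservations(
            "env", {"formic": rng.normal(-23, 1, 6), "acetic": rng.normal(-25, 1, 6)}
        )
        chain = ChainConfig(n_retained=25_000, n_burnin=5_000, seed=31)
        p = fit_mixing_model(obs, four_sources, chain=chain)
        perm = [2, 0, 3, 1]
        p_perm = fit_mixing_model(
            obs, [four_sources[i] for i in perm], chain=chain
        )
        assert p_perm.source_names == tuple(four_sources[i].name for i in perm)
        # MCMC in simplex coordinates is not permutation-equivariant draw by
        # draw; summaries must agree within Monte Carlo error.
        assert p_perm.mean == pytest.approx(p.mean[perm], abs=0.03)
        assert p_perm.sd == pytest.approx(p.sd[perm], abs=0.03)

    def test_true_fraction_recovered_within_ci(self, four_sources):
        from isomix import ScenarioConfig, generate_environment_samples

        cfg = ScenarioConfig(
            sources=four_sources,
            true_fractions=np.array([[0.15, 0.2, 0.3, 0.35]]),
            n_replicates=6,
            seed=404,
        )
        obs, truth = generate_environment_samples(cfg)
        post = fit_mixing_model(
            obs[0], four_sources, chain=ChainConfig(n_retained=6000, n_burnin=3000, seed=404)
        )
        true_F = truth["true_fraction"].to_numpy()
        inside = (post.ci95[:, 0] <= true_F) & (true_F <= post.ci95[:, 1])
        assert inside.sum() >= 3  # at most one marginal miss in a single fit

    def test_tracer_mismatch_rejected(self, four_sources):
        obs = MixtureObservations("env", {"propionic": [-25.0]})
        with pytest.raises(ValueError):
            fit_mixing_model(obs, four_sources)

    def test_acetic_only_mode(self, four_sources, rng):
        obs = MixtureObservations(
            "env", {"formic": rng.normal(-23, 1, 5), "acetic": rng.normal(-25, 1, 5)}
        )
        post = fit_mixing_model(
            obs,
            four_sources,
            chain=ChainConfig(n_retained=1500, n_burnin=800, seed=8),
            tracers=["acetic"],
        )
        assert post.draws.shape[1] == 4
        assert np.allclose(post.draws.sum(axis=1), 1.0, atol=1e-9)


class TestSummaries:
    def test_constant_draws_have_zero_sd(self):
        post = _posterior_from_draws(np.tile([0.2, 0.3, 0.5], (50, 1)))
        s = summarize_posterior(post)
        assert np.allclose(s["sd"], 0.0)
        assert np.allclose(s["mean"], [0.2, 0.3, 0.5])

    def test_dirichlet_moments_match_closed_form(self, rng):
        alphas = np.array([2.0, 3.0, 5.0])
        draws = rng.dirichlet(alphas, size=20000)
        s = summarize_posterior(_posterior_from_draws(draws))
        a0 = alphas.sum()
        mean = alphas / a0
        sd = np.sqrt(alphas * (a0 - alphas) / (a0**2 * (a0 + 1)))
        assert s["mean"].to_numpy() == pytest.approx(mean, abs=0.005)
        assert s["sd"].to_numpy() == pytest.approx(sd, abs=0.005)


class TestPropagation:
    def test_single_environment_returns_itself(self, rng):
        draws = rng.dirichlet([2.0, 5.0], size=4000)
        post = _posterior_from_draws(draws)
        pooled = propagate_across_replicates([post], seed=1)
        assert pooled.mean == pytest.approx(post.mean)
        assert pooled.sd == pytest.approx(post.sd, rel=0.1)

    def test_identical_environments_shrink_sd(self, rng):
        draws = rng.dirichlet([2.0, 5.0], size=4000)
        post = _posterior_from_draws(draws)
        pooled = propagate_across_replicates([post, post], seed=1)
        assert pooled.mean == pytest.approx(post.mean)
        assert np.all(pooled.sd <= post.sd)
        # independent resampling of two copies halves the variance
        assert pooled.sd == pytest.approx(post.sd / np.sqrt(2), rel=0.1)

    def test_deterministic_under_seed(self, rng):
        posts = [
            _posterior_from_draws(rng.dirichlet([1, 1, 1], size=500))
            for _ in range(3)
        ]
        a = propagate_across_replicates(posts, seed=7)
        b = propagate_across_replicates(posts, seed=7)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_mismatched_source_sets_rejected(self, rng):
        a = _posterior_from_draws(rng.dirichlet([1, 1], size=10), names=("x", "y"))
        b = _posterior_from_draws(rng.dirichlet([1, 1], size=10), names=("x", "z"))
        with pytest.raises(ValueError, match="source sets"):
            propagate_across_replicates([a, b])


class TestValidation:
    def test_single_source_rejected(self):
        with pytest.raises(ValueError, match="2 sources"):
            IsotopeMixingModel(source_means=[[-20.0]], source_sds=[[1.0]]).fit(
                [[-20.0]]
            )

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            IsotopeMixingModel(
                source_means=[[-20.0], [-30.0]], source_sds=[[-1.0], [1.0]]
            ).fit([[-25.0]])

    def test_sklearn_params_round_trip(self):
        m = IsotopeMixingModel(n_retained=123, random_state=9)
        assert m.get_params()["n_retained"] == 123
        m.set_params(n_burnin=77)
        assert m.n_burnin == 77
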