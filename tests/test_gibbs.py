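"""Gibbs sampler components: latent draws, conjugate updates, oracle checks."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from sexratio import (
    CycleDataset,
    LatentCounts,
    MCMCConfig,
    ModelParameters,
    PriorSpec,
    ValidationError,
    brute_force_posterior,
    run_chain,
    sample_latent_counts,
    sample_truncated_poisson,
    update_gamma,
    update_lambda,
)
from sexratio.gibbs import pointmass_probability

from conftest import make_cycle


def params(lam=0.5, gam=(1.0, 1.0, 1.0)):
    lam = np.full(12, lam) if np.isscalar(lam) else np.asarray(lam)
    return ModelParameters(lam=lam, gam=np.asarray(gam))


class TestTruncatedPoisson:
    def test_support_is_positive(self, rng):
        for rate in (0.001, 0.5, 2.0, 20.0, 80.0):
            draws = sample_truncated_poisson(np.full(2000, rate), rng)
            assert draws.min() >= 1

    def test_mean_matches_closed_form(self, rng):
        draws = sample_truncated_poisson(np.full(100_000, 2.0), rng)
        expected = 2.0 / (1 - np.exp(-2.0))
        # var of truncated Poisson(2): E[N^2] - mean^2
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 4 * se

    def test_small_rate_degenerates_to_one(self, rng):
        draws = sample_truncated_poisson(np.full(50_000, 1e-4), rng)
        assert (draws == 1).mean() > 0.9999

    def test_scalar_interface(self, rng):
        assert isinstance(sample_truncated_poisson(1.5, rng), int)

    @pytest.mark.parametrize("rate", [0.0, -1.0, np.inf, np.nan])
    def test_invalid_rates(self, rate, rng):
        with pytest.raises(ValidationError):
            sample_truncated_poisson(rate, rng)


class TestLatentCounts:
    def test_all_female_gives_zero_counts(self, rng):
        data = CycleDataset([make_cycle(i, sex=1, days=(0, 1)) for i in range(10)])
        latent = sample_latent_counts(params(), data, rng)
        assert latent.W.sum() == 0
        assert latent.consistent_with(data.sexes())

    def test_single_day_male_concentrates(self, rng):
        data = CycleDataset([make_cycle(0, sex=0, days=(-3,))])
        latent = sample_latent_counts(params(), data, rng)
        k = -3 + 8  # 0-based column of day -3
        assert latent.W[0, k] >= 1
        assert latent.W[0].sum() == latent.W[0, k]

    def test_multinomial_allocation_shares(self, rng):
        # one male cycle replicated 100k times; lambda ratio 3:1 on two days
        lam = np.full(12, 0.2)
        lam[4], lam[8] = 0.6, 0.2
        data = CycleDataset([make_cycle(i, sex=0, days=(-4, 0)) for i in range(100_000)])
        latent = sample_latent_counts(params(lam=lam), data, rng)
        total = latent.W.sum()
        share = latent.W[:, 4].sum() / total
        se = np.sqrt(0.75 * 0.25 / total)
        assert abs(share - 0.75) < 4 * se
        assert latent.consistent_with(data.sexes())

    def test_counts_matrix_validation(self):
        with pytest.raises(ValidationError):
            LatentCounts(W=-np.ones((3, 12), dtype=int))


class TestLambdaUpdate:
    def test_no_data_draws_from_prior(self, rng):
        data = CycleDataset([make_cycle(0, sex=1, days=(0,))])
        latent = LatentCounts(W=np.zeros((1, 12), dtype=int))
        priors = PriorSpec(a0k=np.full(12, 3.0), b0k=np.full(12, 2.0),
                           pi_h=np.full(3, 0.5), a0h=np.ones(3), b0h=np.ones(3))
        # day -8 has no intercourse in this dataset: pure prior for that day
        draws = np.array([update_lambda(latent, params(), data, priors, rng)[0]
                          for _ in range(20_000)])
        se = np.sqrt(3.0) / 2.0 / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.5) < 4 * se

    def test_conjugate_posterior_moments(self, rng):
        # a0 = b0 = 1, sum W = 3 on day 0, exposure sum = 2 -> Gamma(4, 3)
        data = CycleDataset([make_cycle(i, sex=0, days=(0,)) for i in range(2)])
        W = np.zeros((2, 12), dtype=int)
        W[0, 8], W[1, 8] = 2, 1
        latent = LatentCounts(W=W)
        priors = PriorSpec.default()
        draws = np.array([update_lambda(latent, params(), data, priors, rng)[8]
                          for _ in range(20_000)])
        se = np.sqrt(4.0) / 3.0 / np.sqrt(draws.size)
        assert abs(draws.mean() - 4.0 / 3.0) < 4 * se


class TestGammaUpdate:
    def test_no_information_keeps_prior_mass(self):
        for pi in (0.2, 0.5, 0.794):
            assert pointmass_probability(0.0, 0.0, pi, 0.1, 0.1) == pytest.approx(pi)

    def test_class_one_only_data_draws_prior(self, rng):
        data = CycleDataset([make_cycle(i, sex=0, days=(0,), foll_len=10)
                             for i in range(5)])
        latent = sample_latent_counts(params(), data, rng)
        priors = PriorSpec.default()
        gams = np.array([update_gamma(latent, params(), data, priors, rng)
                         for _ in range(4000)])
        frac_null = (gams == 1.0).mean(axis=0)
        se = np.sqrt(priors.pi_h * (1 - priors.pi_h) / 4000)
        assert np.all(np.abs(frac_null - priors.pi_h) < 4 * se)

    def test_mixture_weight_against_quadrature(self, rng):
        # 1-D numerical integration of the continuous branch as the oracle
        for _ in range(100):
            A = float(rng.integers(0, 30))
            B = float(rng.uniform(0.01, 20.0))
            a0 = float(rng.uniform(0.05, 3.0))
            b0 = float(rng.uniform(0.05, 3.0))
            pi = float(rng.uniform(0.05, 0.95))
            dens = gamma_dist(a0, scale=1.0 / b0).pdf
            integrand = lambda g: g ** A * np.exp(-g * B) * dens(g)
            I0, _ = quad(integrand, 0, np.inf, limit=200)
            expected = pi * np.exp(-B) / (pi * np.exp(-B) + (1 - pi) * I0)
            assert pointmass_probability(A, B, pi, a0, b0) == pytest.approx(
                expected, rel=1e-3, abs=1e-9)  # limited by quad accuracy

    def test_log_space_stability_at_huge_counts(self):
        # must not overflow at latent-count sums up to 1e4
        for A, B in [(1e4, 1e4), (1e4, 1.0), (5e3, 2e3), (0.0, 1e4)]:
            p = pointmass_probability(A, B, 0.5, 0.1, 0.1)
            assert np.isfinite(p) and 0.0 <= p <= 1.0


class TestRunChain:
    def test_seeded_determinism(self, small_synthetic):
        cfg = MCMCConfig(burn_in=50, iterations=200, chains=2, seed=9)
        s1 = run_chain(small_synthetic, config=cfg, log_every=0)
        s2 = run_chain(small_synthetic, config=cfg, log_every=0)
        assert np.array_equal(s1.lam, s2.lam)
        assert np.array_equal(s1.gam, s2.gam)

    def test_point_mass_closure(self, small_synthetic):
        priors = PriorSpec(a0k=np.ones(12), b0k=np.ones(12), pi_h=np.ones(3),
                           a0h=np.full(3, 0.1), b0h=np.full(3, 0.1))
        s = run_chain(small_synthetic, priors,
                      MCMCConfig(burn_in=20, iterations=100, chains=1, seed=2),
                      log_every=0)
        assert (s.gam == 1.0).all()

    def test_thinning_bookkeeping(self, small_synthetic):
        s = run_chain(small_synthetic,
                      config=MCMCConfig(burn_in=10, iterations=100, chains=1,
                                        seed=0, thin=5), log_every=0)
        assert s.n_kept == 20

    def test_no_covariate_omits_gamma(self, small_synthetic):
        s = run_chain(small_synthetic, covariate=False,
                      config=MCMCConfig(burn_in=10, iterations=50, chains=1, seed=0),
                      log_every=0)
        assert s.gam is None
        assert "gamma_1" not in s.parameter_names

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            MCMCConfig(burn_in=-1)
        with pytest.raises(ValidationError):
            MCMCConfig(iterations=10, thin=20)

    def test_long_format_round_trip(self, small_synthetic):
        from sexratio.gibbs import PosteriorSamples
        s = run_chain(small_synthetic,
                      config=MCMCConfig(burn_in=10, iterations=60, chains=2, seed=4),
                      log_every=0)
        df = s.to_dataframe()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(df) == 2 * 60 * 15
        back = PosteriorSamples.from_dataframe(df)
        assert np.allclose(back.lam, s.lam)
        assert np.allclose(back.gam, s.gam)


class TestBruteForceOracle:
    def test_empty_dataset_returns_prior(self):
        priors = PriorSpec.default()
        out = brute_force_posterior(CycleDataset([]), priors)
        assert np.allclose(out["lam_mean"], priors.a0k / priors.b0k)
        assert np.allclose(out["p_gamma_eq_1"], priors.pi_h)

    def test_conjugate_closed_form(self):
        # all-female cycles on one day: likelihood exp(-n lam), conjugate
        # posterior Gamma(a0, b0 + n) with mean a0 / (b0 + n)
        n = 6
        data = CycleDataset([make_cycle(i, sex=1, days=(0,), foll_len=10)
                             for i in range(n)])
        out = brute_force_posterior(data, n_grid=400)
        assert out["lam_mean"][8] == pytest.approx(1.0 / (1.0 + n), rel=1e-3)

    def test_refinement_converges(self):
        data = CycleDataset(
            [make_cycle(i, sex=i % 2, days=(-4, 0)[: 1 + i % 2], foll_len=10)
             for i in range(12)]
        )
        means = [brute_force_posterior(data, n_grid=m)["lam_mean"][4]
                 for m in (25, 50, 100)]
        d1, d2 = abs(means[1] - means[0]), abs(means[2] - means[1])
        assert d2 <= d1 + 1e-9

    def test_refuses_high_dimension(self, small_synthetic):
        with pytest.raises(ValidationError):
            brute_force_posterior(small_synthetic)
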