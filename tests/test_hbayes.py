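import numpy as np
import pytest
from scipy.special import gammaln

from arealrisk.areal_core import SpatialWeights
from arealrisk.errors import DomainError
from arealrisk.hbayes import (
    McmcConfig,
    ModelSpec,
    car_log_prior,
    dic,
    fit,
    gelman_rubin,
    log_likelihood,
    posterior_summary,
    table3_models,
)
from arealrisk.standardization import CountTable

from .conftest import make_table


def single_area_table(observed, expected):
    return CountTable(area_ids=["a"], observed=np.array([observed], float),
                      population=np.array([1000.0]),
                      expected=np.array([expected], float))


class TestLogLikelihood:
    def test_single_area_poisson_pmf_oracle(self):
        # O = 3, mu = 2: independent Poisson log-pmf
        t = single_area_table(3, 2.0)
        expected = -2.0 + 3 * np.log(2.0) - np.log(6.0)
        assert log_likelihood(t, {}) == pytest.approx(expected)
        # scipy cross-check
        from scipy.stats import poisson

        assert log_likelihood(t, {}) == pytest.approx(poisson.logpmf(3, 2.0))

    def test_saturated_model_is_maximal(self):
        t = single_area_table(5, 3.0)
        alpha_sat = np.log(5.0 / 3.0)  # mu = O
        best = log_likelihood(t, {"alpha0": alpha_sat})
        for eps in (-0.3, -0.05, 0.05, 0.3):
            assert log_likelihood(t, {"alpha0": alpha_sat + eps}) < best

    def test_zero_components_mean_mu_equals_e(self):
        t = single_area_table(4, 4.0)
        ll = log_likelihood(t, {"alpha0": 0.0, "u": np.zeros(1), "s": np.zeros(1)})
        assert ll == pytest.approx(-4.0 + 4 * np.log(4.0) - gammaln(5.0))

    def test_nonfinite_predictor_rejected(self):
        t = single_area_table(4, 4.0)
        with pytest.raises(DomainError):
            log_likelihood(t, {"alpha0": np.inf})

    def test_model5_state_collapses_to_model3(self):
        # with S = 0 the model-5 likelihood equals the model-3 likelihood
        rng = np.random.default_rng(0)
        t = CountTable(area_ids=[f"a{i}" for i in range(6)],
                       observed=rng.poisson(10, 6).astype(float),
                       population=np.full(6, 100.0),
                       expected=np.full(6, 10.0))
        u = rng.normal(0, 0.2, 6)
        p5 = {"alpha0": 0.1, "u": u, "s": np.zeros(6)}
        p3 = {"alpha0": 0.1, "u": u}
        assert log_likelihood(t, p5) == pytest.approx(log_likelihood(t, p3))


class TestCarLogPrior:
    @pytest.fixture()
    def pair(self):
        return SpatialWeights(ids=["a", "b"], neighbors={"a": ["b"], "b": ["a"]})

    def test_constant_vector_zero(self, pair):
        assert car_log_prior([3.0, 3.0], pair, 1.0, "gaussian_icar") == 0.0
        assert car_log_prior([3.0, 3.0], pair, 1.0, "l1") == 0.0

    def test_single_pair_hand_values(self, pair):
        assert car_log_prior([0.0, 2.0], pair, 1.0, "gaussian_icar") == pytest.approx(-2.0)
        assert car_log_prior([0.0, 2.0], pair, 1.0, "l1") == pytest.approx(-2.0)

    def test_sigma_nonpositive_rejected(self, pair):
        with pytest.raises(DomainError):
            car_log_prior([0.0, 1.0], pair, 0.0)

    def test_shift_invariance(self, pair):
        a = car_log_prior([0.3, 1.1], pair, 0.7, "l1")
        b = car_log_prior([10.3, 11.1], pair, 0.7, "l1")
        assert a == pytest.approx(b)

    def test_icar_full_conditional_moments(self):
        # s_i | rest ~ N(neighbor mean, sigma^2 / d_i): neighbors (1, 3)
        w = SpatialWeights(
            ids=["i", "j", "k"],
            neighbors={"i": ["j", "k"], "j": ["i"], "k": ["i"]},
        )
        sigma = 0.8
        grid = np.linspace(-2, 6, 41)
        logp = np.array([
            car_log_prior([si, 1.0, 3.0], w, sigma, "gaussian_icar")
            for si in grid
        ])
        coeffs = np.polyfit(grid, logp, 2)  # exact quadratic
        mean = -coeffs[1] / (2 * coeffs[0])
        var = -1.0 / (2 * coeffs[0])
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(sigma**2 / 2)


class TestDic:
    def test_printed_identity_model5(self):
        dbar, dhat, pd_, dic_ = dic([316.465], 273.777)
        assert pd_ == pytest.approx(42.688)
        assert dic_ == pytest.approx(359.153)

    def test_printed_identity_model4(self):
        dbar, dhat, pd_, dic_ = dic([334.725], 291.671)
        assert pd_ == pytest.approx(43.054)
        assert dic_ == pytest.approx(377.779)

    def test_degenerate_equal(self):
        dbar, dhat, pd_, dic_ = dic([100.0, 100.0], 100.0)
        assert pd_ == 0.0
        assert dic_ == 100.0


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 5000))
        assert 0.99 <= gelman_rubin(chains) <= 1.05

    def test_disjoint_chains_large(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(-10, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 1.2

    def test_constant_identical_chains_warns(self):
        with pytest.warns(UserWarning):
            assert gelman_rubin(np.ones((2, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="n_chains"):
            gelman_rubin(np.ones((1, 100)))


class TestPosteriorSummary:
    def test_constant_samples(self):
        s = posterior_summary(np.full(50, 3.3))
        assert s.mean == pytest.approx(3.3)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.q2_5 == pytest.approx(3.3)
        assert s.q97_5 == pytest.approx(3.3)

    def test_range_brackets_mean(self):
        s = posterior_summary(np.arange(1.0, 101.0))
        assert s.q2_5 < 50.5 < s.q97_5

    def test_normal_sample_clt_bounds(self):
        rng = np.random.default_rng(42)
        s = posterior_summary(rng.normal(size=100_000))
        assert abs(s.mean) < 0.02
        assert abs(s.sd - 1.0) < 0.02
        assert s.mc_error < s.sd


class TestFit:
    def test_conjugate_gamma_oracle(self, shenzhen_dataset):
        lattice, weights, table, truth = shenzhen_dataset
        cfg = McmcConfig(n_chains=3, n_iter=3000, burn_in=500, seed=11)
        res = fit(table, weights, ModelSpec(), cfg)
        lam = np.exp(res.scalar_chains["alpha0"].ravel())
        o_sum, e_sum = table.observed.sum(), table.expected.sum()
        gamma_mean, gamma_sd = o_sum / e_sum, np.sqrt(o_sum) / e_sum
        mc = posterior_summary(lam).mc_error
        assert abs(lam.mean() - gamma_mean) < 3 * mc
        assert abs(lam.std(ddof=1) - gamma_sd) < 3 * mc

    def test_dic_identities_exact(self, shenzhen_dataset):
        lattice, weights, table, truth = shenzhen_dataset
        cfg = McmcConfig(n_chains=2, n_iter=1000, burn_in=200, seed=5)
        res = fit(table, weights, table3_models()[3], cfg)
        assert res.pd == pytest.approx(res.dbar - res.dhat, abs=1e-9)
        assert res.dic == pytest.approx(res.dbar + res.pd, abs=1e-9)

    def test_intercept_only_pd_near_one(self, shenzhen_dataset):
        lattice, weights, table, truth = shenzhen_dataset
        cfg = McmcConfig(n_chains=2, n_iter=2000, burn_in=500, seed=6)
        res = fit(table, weights, ModelSpec(), cfg)
        assert 0.5 < res.pd < 1.5  # one free parameter

    def test_deterministic_under_seed(self, shenzhen_dataset):
        lattice, weights, table, truth = shenzhen_dataset
        cfg = McmcConfig(n_chains=2, n_iter=600, burn_in=200, seed=9)
        a = fit(table, weights, table3_models()[3], cfg)
        b = fit(table, weights, table3_models()[3], cfg)
        np.testing.assert_array_equal(a.scalar_chains["alpha0"],
                                      b.scalar_chains["alpha0"])
        np.testing.assert_array_equal(a.smoothed_sr, b.smoothed_sr)
        assert a.dic == b.dic

    def test_model5_smoothing_properties(self, shenzhen_dataset):
        lattice, weights, table, truth = shenzhen_dataset
        cfg = McmcConfig(n_chains=2, n_iter=1500, burn_in=500, seed=21)
        res = fit(table, weights, table3_models()[5], cfg)
        raw_sr = table.observed / table.expected
        # smoothed surface stays inside the raw SR range and positive
        assert np.all(res.smoothed_sr > 0)
        assert res.smoothed_sr.min() >= raw_sr.min() - 1e-9
        assert res.smoothed_sr.max() <= raw_sr.max() + 1e-9
        # shrinkage strongest for least-stable estimates (smallest E)
        small = np.argsort(table.expected)[:10]
        assert (np.abs(res.smoothed_sr[small] - 1).mean()
                < np.abs(raw_sr[small] - 1).mean())

    def test_island_held_at_zero_with_warning(self):
        t = CountTable(area_ids=["a", "b", "c"],
                       observed=np.array([10.0, 12.0, 8.0]),
                       population=np.full(3, 100.0),
                       expected=np.array([10.0, 10.0, 10.0]))
        w = SpatialWeights(ids=["a", "b", "c"],
                           neighbors={"a": ["b"], "b": ["a"], "c": []})
        cfg = McmcConfig(n_chains=2, n_iter=300, burn_in=100, seed=2)
        with pytest.warns(UserWarning, match="island"):
            res = fit(t, w, table3_models("gaussian_icar")[4], cfg)
        assert any("island" in msg for msg in res.warnings)

    def test_beta_recovery_single_seed(self):
        from dataclasses import replace

        from arealrisk.standardization import compute_expected
        from arealrisk.synthetic_data import generate, shenzhen_like

        sc = replace(shenzhen_like(seed=4), delta=0.0, sigma=0.0, clusters=[])
        lattice, weights, table, truth = generate(sc)
        table = compute_expected(table)
        cfg = McmcConfig(n_chains=3, n_iter=2000, burn_in=500, seed=14)
        res = fit(table, weights, table3_models()[1], cfg)
        s = res.summaries["beta"]
        assert s.q2_5 <= 0.45 <= s.q97_5
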