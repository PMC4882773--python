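"""Sampler correctness on closed-form reductions, diagnostics and DIC."""

import math

import numpy as np
import pytest
from scipy.special import expit, gammaln

import scmap
from scmap import (
    MCMCConfig,
    ModelStructure,
    SCMData,
    SCMPriors,
    autocorrelation,
    bgr_diagnostic,
    dic,
    run_mcmc,
    sensitivity_run,
    split_rhat,
)
from scmap.regions import build_region_map

FLAT_ONLY = ModelStructure(shared=False, specific=False, contrast=False,
                           covariates=False)


def _one_region_data(O=7, n=10):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = build_region_map(["A"], [])
    return SCMData(m, [[O], [O]], [[n], [n]], np.zeros((2, 1, 0)),
                   covariate_names=())


class TestConjugateReduction:
    """Degenerate intercept-only model against its exact Beta posterior.

    A flat prior on the logit intercept corresponds to the density
    1/(p(1-p)) on the probability scale, so with O=7 of n=10 the posterior
    of p is exactly Beta(7, 3)."""

    @pytest.fixture(scope="class")
    def run(self):
        data = _one_region_data()
        cfg = MCMCConfig(n_chains=2, burn_in=1500, iterations=8000, thin=2,
                         seed=7)
        return data, run_mcmc(data, SCMPriors(), cfg, FLAT_ONLY)

    def test_posterior_mean_and_sd(self, run):
        _, samples = run
        p = expit(samples.stacked("logit_p")[:, 0, 0])
        a, b = 7, 3
        exact_mean = a / (a + b)
        exact_sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        n_eff = p.size / 10  # conservative ESS for the MC error bound
        assert p.mean() == pytest.approx(exact_mean, abs=3 * exact_sd / math.sqrt(n_eff))
        assert p.std() == pytest.approx(exact_sd, abs=0.015)

    def test_effective_parameters_near_one(self, run):
        data, samples = run
        dic_val, pd_val = dic(samples, data)
        # one free intercept per gender, two cells: pD ~ 2
        assert 1.0 < pd_val < 3.0
        assert dic_val == pytest.approx(
            samples.stacked("deviance").mean() + pd_val
        )


def test_prior_only_run_recovers_log_delta_sd(zhejiang):
    """With no data (all n = 0) the sampled log weight reproduces its prior."""
    N = zhejiang.n_regions
    data = SCMData(zhejiang, np.zeros((2, N)), np.zeros((2, N)),
                   np.zeros((2, N, 0)), covariate_names=())
    cfg = MCMCConfig(n_chains=2, burn_in=500, iterations=4000, thin=2, seed=11)
    samples = run_mcmc(data, SCMPriors(), cfg,
                       ModelStructure(covariates=False))
    ld = samples.stacked("log_delta")
    assert abs(ld.mean()) < 0.05
    assert ld.std() == pytest.approx(math.sqrt(0.169), abs=0.04)


def test_seeded_determinism(toy_data):
    cfg = MCMCConfig(n_chains=2, burn_in=200, iterations=200, thin=2, seed=3)
    s1 = run_mcmc(toy_data, SCMPriors(), cfg)
    s2 = run_mcmc(toy_data, SCMPriors(), cfg)
    for key in s1.raw:
        assert np.array_equal(s1.raw[key], s2.raw[key]), key
    assert np.array_equal(s1.stacked("deviance"), s2.stacked("deviance"))


def test_retained_draw_count(toy_data):
    cfg = MCMCConfig(n_chains=2, burn_in=100, iterations=300, thin=3, seed=1)
    s = run_mcmc(toy_data, SCMPriors(), cfg)
    assert s.n_chains == 2 and s.n_draws == 100


def test_missing_covariates_require_imputation(path_map):
    x = np.full((2, 3, 1), np.nan)
    x[:, :2, :] = 0.3
    data = SCMData(path_map, [[1, 1, 1]] * 2, [[9, 9, 9]] * 2, x,
                   covariate_names=("prop_obese",))
    with pytest.raises(ValueError, match="impute_missing"):
        run_mcmc(data, SCMPriors(), MCMCConfig(burn_in=10, iterations=10, thin=1))


def test_imputed_covariate_is_sampled(path_map):
    x = np.full((2, 3, 1), 0.3)
    x[0, 2, 0] = np.nan
    data = SCMData(path_map, [[3, 3, 3]] * 2, [[9, 9, 9]] * 2, x,
                   covariate_names=("prop_obese",))
    data = scmap.impute_missing(data)
    cfg = MCMCConfig(n_chains=2, burn_in=300, iterations=600, thin=2, seed=5)
    s = run_mcmc(data, SCMPriors(), cfg)
    draws = s.raw["x_imputed"][:, :, 0]
    assert draws.std() > 0  # actually resampled, not frozen at the fill


class TestSplitRhat:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 8000))
        assert split_rhat(chains) < 1.01

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert split_rhat(chains) > 1.1

    def test_constant_chains_report_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert split_rhat(np.ones((2, 100))) == 1.0

    def test_single_chain_rejected(self, toy_data):
        cfg = MCMCConfig(n_chains=1, burn_in=50, iterations=50, thin=1, seed=2)
        s = run_mcmc(toy_data, SCMPriors(), cfg)
        with pytest.raises(ValueError, match="chains"):
            bgr_diagnostic(s)

    def test_per_parameter_report(self, toy_data):
        cfg = MCMCConfig(n_chains=2, burn_in=300, iterations=600, thin=2, seed=4)
        s = run_mcmc(toy_data, SCMPriors(), cfg)
        rhat = bgr_diagnostic(s, ["alpha_male", "eta1"])
        assert set(rhat.index) == {"alpha_male", "eta1"}
        assert (rhat > 0.9).all()


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        acf = autocorrelation(rng.normal(size=500), 10)
        assert acf[0] == pytest.approx(1.0)

    def test_white_noise_small_lag_one(self):
        rng = np.random.default_rng(1)
        acf = autocorrelation(rng.normal(size=10_000), 5)
        assert abs(acf[1]) < 0.05

    def test_ar1_process_oracle(self):
        rng = np.random.default_rng(2)
        n, rho = 20_000, 0.5
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        acf = autocorrelation(x, 3)
        assert acf[1] == pytest.approx(rho, abs=0.05)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            acf = autocorrelation(np.ones(100), 5)
        assert acf[0] == 1.0


class TestDIC:
    def test_point_mass_posterior_has_zero_pd(self, toy_data):
        cfg = MCMCConfig(n_chains=2, burn_in=100, iterations=100, thin=1, seed=9)
        s = run_mcmc(toy_data, SCMPriors(), cfg)
        # freeze every draw at one state
        u0 = s.derived["logit_p"][0, 0].copy()
        s.derived["logit_p"][:] = u0
        const = float(np.sum(gammaln(toy_data.n + 1) - gammaln(toy_data.O + 1)
                             - gammaln(toy_data.n - toy_data.O + 1)))
        ll = const + float(np.sum(toy_data.O * u0
                                  - toy_data.n * np.logaddexp(0.0, u0)))
        s.derived["deviance"][:] = -2.0 * ll
        dic_val, pd_val = dic(s, toy_data)
        assert pd_val == pytest.approx(0.0, abs=1e-9)
        assert dic_val == pytest.approx(-2.0 * ll, abs=1e-9)

    def test_nonfinite_deviance_rejected(self, toy_data):
        cfg = MCMCConfig(n_chains=2, burn_in=50, iterations=50, thin=1, seed=9)
        s = run_mcmc(toy_data, SCMPriors(), cfg)
        s.derived["deviance"][0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            dic(s, toy_data)


class TestSensitivity:
    @pytest.fixture(scope="class")
    def small(self):
        m = build_region_map(["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])
        rng = np.random.default_rng(20)
        n = np.full((2, 3), 80)
        O = rng.binomial(n, 0.33)
        x = rng.uniform(0.2, 0.8, size=(2, 3, 1))
        return SCMData(m, O, n, x, covariate_names=("prop_obese",))

    def test_identical_settings_identical_rows(self, small):
        cfg = MCMCConfig(n_chains=2, burn_in=200, iterations=400, thin=2, seed=6)
        res = sensitivity_run(small, [SCMPriors(name="priors1"),
                                      SCMPriors(name="priors1b")], cfg)
        a = res.table.iloc[0].drop(["setting", "priors"])
        b = res.table.iloc[1].drop(["setting", "priors"])
        assert (a == b).all()

    def test_exclusion_reindexes_model(self, small):
        cfg = MCMCConfig(n_chains=2, burn_in=100, iterations=200, thin=2, seed=6)
        res = sensitivity_run(small, [SCMPriors()], cfg, exclusions=["C"])
        assert len(res.table) == 2
        excl = res.samples[[k for k in res.samples if "excl" in k][0]]
        assert excl.region_map.n_regions == 2
        assert excl.raw["ssh"].shape[-1] == 2

    def test_posterior_stability_across_priors(self, small):
        cfg = MCMCConfig(n_chains=2, burn_in=400, iterations=800, thin=2, seed=8)
        res = sensitivity_run(small, [scmap.PRIORS_1, scmap.PRIORS_3], cfg)
        rr = res.table["rr_prop_obese_male"]
        assert abs(rr.iloc[0] - rr.iloc[1]) < 0.05
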