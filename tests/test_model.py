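"""SCM likelihood, priors, derived quantities and imputation rules."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import scmap
from scmap import (
    ModelStructure,
    SCMData,
    SCMParams,
    SCMPriors,
    component_sds,
    covariate_rr,
    impute_missing,
    linear_predictor,
    log_likelihood,
    log_posterior,
    log_prior,
    variance_fractions,
)
from scmap.regions import build_region_map, car_quadratic_form


def _swap_data(data):
    return SCMData(data.region_map, data.O[::-1], data.n[::-1], data.x[::-1],
                   data.covariate_names, data.covariate_scale)


class TestLinearPredictor:
    def test_zero_state_gives_half(self, toy_data):
        params = SCMParams.zeros(3, 2)
        p = linear_predictor(params, toy_data)
        assert np.allclose(p, 0.5)

    def test_delta_one_symmetric_eta(self, toy_data, toy_params):
        params = toy_params
        params.log_delta = 0.0
        params.bind[:] = 0.0
        params.bspat[:] = 0.0
        params.gamma_contrast[:] = 0.0
        eta = params.eta()
        assert np.allclose(eta[0], eta[1])

    def test_hand_evaluation_three_regions(self, toy_data, toy_params):
        p = linear_predictor(toy_params, toy_data)
        d = math.exp(toy_params.log_delta)
        for j in range(2):
            for i in range(3):
                phi = toy_params.ush[i] + toy_params.ssh[i]
                shared = d * phi if j == 0 else phi / d
                contrast = 0.0 if j == 0 else toy_params.gamma_contrast[i]
                lin = (toy_params.alpha[j]
                       + sum(toy_params.b[j, k] * toy_data.x[j, i, k] * 100.0
                             for k in range(2))
                       + shared + contrast
                       + toy_params.bind[j, i] + toy_params.bspat[j, i])
                assert p[j, i] == pytest.approx(1 / (1 + math.exp(-lin)), rel=1e-12)

    def test_probabilities_strictly_interior(self, toy_data, toy_params):
        p = linear_predictor(toy_params, toy_data)
        assert np.all((p > 0) & (p < 1))

    def test_nonfinite_state_rejected(self, toy_data, toy_params):
        toy_params.alpha[0] = np.inf
        with pytest.raises(FloatingPointError):
            linear_predictor(toy_params, toy_data)


class TestLogLikelihood:
    def test_single_cell_closed_form(self):
        m = build_region_map(["A"], [])
        data = SCMData(m, [[1], [1]], [[2], [2]], np.zeros((2, 1, 0)),
                       covariate_names=())
        params = SCMParams.zeros(1, 0)
        # each cell: log C(2,1) + log(0.25) = log(0.5); two cells
        assert log_likelihood(params, data) == pytest.approx(2 * math.log(0.5))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_cellwise_binom_logpmf(self, toy_data, toy_params, seed):
        ll = log_likelihood(toy_params, toy_data)
        p = linear_predictor(toy_params, toy_data)
        oracle = sum(
            stats.binom.logpmf(toy_data.O[j, i], toy_data.n[j, i], p[j, i])
            for j in range(2) for i in range(3)
        )
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_extreme_state_finite(self, toy_data):
        params = SCMParams.zeros(3, 2)
        params.alpha[:] = [30.0, -30.0]
        ll = log_likelihood(params, toy_data)
        assert math.isfinite(ll) and ll < -100


class TestLogPrior:
    def _oracle(self, params, priors, rmap, structure=ModelStructure()):
        N, C = rmap.n_regions, rmap.n_components
        a, r = priors.precision_shape, priors.precision_rate
        lp = stats.norm.logpdf(params.log_delta, 0,
                               math.sqrt(priors.log_delta_variance))

        def car(v, tau):
            q = car_quadratic_form(np.asarray(v), rmap)
            return 0.5 * (N - C) * math.log(tau / (2 * math.pi)) - 0.5 * tau * q

        def iid(v, tau):
            return float(np.sum(stats.norm.logpdf(v, 0, 1 / math.sqrt(tau))))

        gam = lambda t: stats.gamma.logpdf(t, a, scale=1 / r)
        if structure.shared:
            lp += car(params.ssh, params.tau_ssh) + iid(params.ush, params.tau_ush)
            lp += gam(params.tau_ssh) + gam(params.tau_ush)
        if structure.specific:
            for j in range(2):
                lp += car(params.bspat[j], params.tau_bspat[j])
                lp += iid(params.bind[j], params.tau_bind[j])
                lp += gam(params.tau_bspat[j]) + gam(params.tau_bind[j])
        if structure.contrast:
            lp += car(params.gamma_contrast, params.tau_gamma)
            lp += gam(params.tau_gamma)
        return float(lp)

    def test_zero_state_scalar_oracle(self, path_map):
        params = SCMParams.zeros(3, 2)
        priors = SCMPriors()
        assert log_prior(params, priors, path_map) == pytest.approx(
            self._oracle(params, priors, path_map), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_random_states_match_oracle(self, path_map, toy_params, seed):
        priors = SCMPriors(2.0, 1e-3)
        assert log_prior(toy_params, priors, path_map) == pytest.approx(
            self._oracle(toy_params, priors, path_map), rel=1e-10
        )

    def test_doubling_tau_changes_car_term_linearly(self, path_map, toy_params):
        priors = SCMPriors()
        q = car_quadratic_form(toy_params.ssh, path_map)
        lp1 = log_prior(toy_params, priors, path_map)
        tau1 = toy_params.tau_ssh
        toy_params.tau_ssh = 2 * tau1
        lp2 = log_prior(toy_params, priors, path_map)
        from scipy.stats import gamma as gamma_dist
        dof = path_map.n_regions - path_map.n_components
        expected = (-0.5 * tau1 * q + 0.5 * dof * math.log(2)
                    + gamma_dist.logpdf(2 * tau1, 1.0, scale=1e4)
                    - gamma_dist.logpdf(tau1, 1.0, scale=1e4))
        assert lp2 - lp1 == pytest.approx(expected, rel=1e-9)

    def test_constant_shift_leaves_car_term(self, path_map, toy_params):
        priors = SCMPriors()
        lp1 = log_prior(toy_params, priors, path_map)
        # shifting the CAR-distributed contrast surface changes nothing in
        # its (intrinsic) CAR term
        toy_params.gamma_contrast = toy_params.gamma_contrast + 5.0
        lp2 = log_prior(toy_params, priors, path_map)
        assert lp2 == pytest.approx(lp1, rel=1e-9)

    def test_nonpositive_precision_rejected(self, path_map, toy_params):
        with pytest.raises(ValueError):
            SCMParams(
                alpha=toy_params.alpha, b=toy_params.b, log_delta=0.0,
                ush=toy_params.ush, ssh=toy_params.ssh, bind=toy_params.bind,
                bspat=toy_params.bspat, gamma_contrast=toy_params.gamma_contrast,
                tau_ssh=-1.0,
            )


class TestLogPosterior:
    @pytest.mark.parametrize("seed", range(3))
    def test_end_to_end_oracle(self, toy_data, toy_params, seed):
        priors = SCMPriors()
        lp = log_posterior(toy_params, toy_data, priors)
        oracle = (log_likelihood(toy_params, toy_data)
                  + log_prior(toy_params, priors, toy_data.region_map))
        assert lp == pytest.approx(oracle, rel=1e-12)

    def test_better_fit_increases_posterior(self, path_map):
        n = np.full((2, 3), 100)
        O = np.full((2, 3), 50)
        data = SCMData(path_map, O, n, np.zeros((2, 3, 0)), covariate_names=())
        good = SCMParams.zeros(3, 0)           # p = 0.5 everywhere, exact fit
        bad = SCMParams.zeros(3, 0)
        bad.alpha[:] = 2.0
        priors = SCMPriors()
        assert log_posterior(good, data, priors) > log_posterior(bad, data, priors)


class TestDerivedQuantities:
    def test_all_shared_gives_eta_one(self):
        p = SCMParams.zeros(3, 0)
        p.ssh = np.array([1.0, -1.0, 0.0])
        assert variance_fractions(p) == (1.0, 1.0)

    def test_constant_phi_gives_eta_zero(self):
        p = SCMParams.zeros(3, 0)
        p.bind = np.array([[0.5, -0.5, 0.0], [0.3, -0.3, 0.0]])
        eta1, eta2 = variance_fractions(p)
        assert eta1 == 0.0 and eta2 == 0.0

    def test_hand_variance_arithmetic(self):
        p = SCMParams.zeros(3, 0)
        p.ssh = np.array([1.0, -1.0, 0.0])  # phi, delta = 1
        p.bind = np.array([[0.5, -0.5, 0.0], [0.0, 0.0, 0.0]])
        eta1, eta2 = variance_fractions(p)
        assert eta1 == pytest.approx(1 / 1.25)
        assert eta2 == pytest.approx(1.0)

    def test_degenerate_state_warns(self):
        p = SCMParams.zeros(3, 0)
        with pytest.warns(UserWarning, match="degenerate"):
            eta1, eta2 = variance_fractions(p)
        assert (eta1, eta2) == (0.0, 0.0)

    def test_eta_in_unit_interval_random_states(self, toy_params):
        eta1, eta2 = variance_fractions(toy_params)
        assert 0.0 <= eta1 <= 1.0 and 0.0 <= eta2 <= 1.0

    def test_component_sd_convention(self):
        p = SCMParams.zeros(3, 0)
        p.ssh = np.array([1.0, -1.0, 0.0])
        assert component_sds(p)["sigma_str"] == pytest.approx(1.0)

    def test_component_sd_scaling(self, toy_params):
        base = component_sds(toy_params)["sigma_unstr"]
        toy_params.ush = 3.0 * toy_params.ush
        assert component_sds(toy_params)["sigma_unstr"] == pytest.approx(3 * base)

    def test_zero_components_zero_sds(self):
        sds = component_sds(SCMParams.zeros(4, 0))
        assert all(v == 0.0 for v in sds.values())

    def test_weight_product_is_one(self, toy_params):
        w1, w2 = toy_params.weights
        assert w1 * w2 == pytest.approx(1.0, rel=1e-15)


class TestGenderSwapSymmetry:
    def test_likelihood_invariant_at_zero_contrast(self, toy_data, toy_params):
        toy_params.gamma_contrast[:] = 0.0
        ll = log_likelihood(toy_params, toy_data)
        swapped = SCMParams(
            alpha=toy_params.alpha[::-1].copy(), b=toy_params.b[::-1].copy(),
            log_delta=-toy_params.log_delta,
            ush=toy_params.ush, ssh=toy_params.ssh,
            bind=toy_params.bind[::-1].copy(), bspat=toy_params.bspat[::-1].copy(),
            gamma_contrast=np.zeros(3),
        )
        assert log_likelihood(swapped, _swap_data(toy_data)) == pytest.approx(
            ll, rel=1e-12
        )


class TestImputation:
    def test_missing_covariate_prior_mean_variance(self, path_map):
        x = np.full((2, 3, 1), np.nan)
        x[0, :, 0] = [0.2, 0.4, np.nan]
        x[1, :, 0] = [0.3, 0.5, 0.4]
        data = SCMData(path_map, [[1, 1, 1]] * 2, [[10, 10, 10]] * 2, x,
                       covariate_names=("prop_obese",))
        out = impute_missing(data)
        (m, v), = [out.imputation_priors[(0, 2, 0)]]
        assert m == pytest.approx(0.3)
        assert v == pytest.approx(0.02)

    def test_no_missing_is_identity(self, toy_data):
        out = impute_missing(toy_data)
        assert np.array_equal(out.O, toy_data.O)
        assert np.array_equal(out.x, toy_data.x)
        assert out.imputation_priors == {}

    def test_substitution_uses_rounded_averages(self, path_map):
        data = SCMData(
            path_map, [[10, 20, 3]] * 2, [[50, 61, 9]] * 2, np.zeros((2, 3, 0)),
            covariate_names=(), substituted_regions=frozenset({"C"}),
        )
        out = impute_missing(data)
        assert out.O[0, 2] == 15           # mean(10, 20)
        assert out.n[0, 2] == 56           # round(mean(50, 61)) = round(55.5)
        assert np.array_equal(out.O[:, :2], data.O[:, :2])

    def test_all_missing_covariate_rejected(self, path_map):
        x = np.full((2, 3, 1), np.nan)
        data = SCMData(path_map, [[1, 1, 1]] * 2, [[10, 10, 10]] * 2, x,
                       covariate_names=("prop_obese",))
        with pytest.raises(ValueError, match="missing in all regions"):
            impute_missing(data)


class TestCovariateRR:
    def _samples_from_b(self, draws):
        """Minimal PosteriorSamples with given b draws for one covariate."""
        import scmap.model as mod
        c, d = 1, len(draws)
        N = 2
        raw = {
            "alpha": np.zeros((c, d, 2)), "b": np.zeros((c, d, 2, 1)),
            "log_delta": np.zeros((c, d)), "ush": np.zeros((c, d, N)),
            "ssh": np.zeros((c, d, N)), "bind": np.zeros((c, d, 2, N)),
            "bspat": np.zeros((c, d, 2, N)), "gamma_contrast": np.zeros((c, d, N)),
            "tau_ssh": np.ones((c, d)), "tau_ush": np.ones((c, d)),
            "tau_gamma": np.ones((c, d)), "tau_bspat": np.ones((c, d, 2)),
            "tau_bind": np.ones((c, d, 2)),
        }
        raw["b"][0, :, 0, 0] = draws
        derived = {k: np.zeros((c, d)) for k in
                   ("eta1", "eta2", "delta", "delta_sq", "deviance",
                    "sigma_str", "sigma_unstr")}
        derived["sigma_ind"] = np.zeros((c, d, 2))
        derived["sigma_spat"] = np.zeros((c, d, 2))
        derived["eta_cells"] = np.zeros((c, d, 2, N))
        derived["logit_p"] = np.zeros((c, d, 2, N))
        rmap = build_region_map(["A", "B"], [("A", "B")])
        return mod.PosteriorSamples(rmap, ("prop_obese",), raw, derived, {})

    def test_zero_draws_give_unit_rr(self):
        s = self._samples_from_b(np.zeros(100))
        assert covariate_rr(s, "prop_obese", "male") == (1.0, 1.0, 1.0)

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(3)
        mu, sigma = 0.05, 0.1
        draws = rng.normal(mu, sigma, 40_000)
        mean, lo, hi = covariate_rr(self._samples_from_b(draws), "prop_obese",
                                    "male")
        assert mean == pytest.approx(math.exp(mu + sigma**2 / 2), rel=5e-3)
        assert lo == pytest.approx(math.exp(mu - 1.96 * sigma), rel=5e-3)

    def test_unknown_covariate_rejected(self):
        s = self._samples_from_b(np.zeros(10))
        with pytest.raises(ValueError):
            covariate_rr(s, "prop_banana", "male")


def test_data_validation():
    m = build_region_map(["A", "B"], [("A", "B")])
    with pytest.raises(ValueError, match="exceed"):
        SCMData(m, [[5, 1], [1, 1]], [[4, 10], [10, 10]], np.zeros((2, 2, 0)),
                covariate_names=())
    with pytest.raises(ValueError, match="proportions"):
        SCMData(m, [[1, 1], [1, 1]], [[10, 10], [10, 10]],
                np.full((2, 2, 1), 1.5), covariate_names=("prop_obese",))
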