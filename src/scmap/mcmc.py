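"""Posterior simulation for the shared component model.

A Metropolis-within-Gibbs sampler: precisions get conjugate gamma Gibbs
updates from their CAR / normal quadratic forms, everything else
(intercepts, coefficients, the log shared weight, every random-effect site
and any imputed covariate) gets scalar random-walk Metropolis updates whose
step sizes adapt during burn-in only.  Sum-to-zero recentring is applied
after every component sweep, with the subtracted mean transferred into the
gender intercepts so the fitted probabilities are untouched.

Also here: split-chain potential scale reduction (R-hat), sample
autocorrelation, DIC with the plug-in taken at the posterior mean of the
linear predictor, and the prior-sensitivity / region-exclusion harness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ModelStructure,
    PosteriorSamples,
    SCMData,
    SCMPriors,
    covariate_rr,
    impute_missing,
)
from .regions import GENDERS

__all__ = [
    "MCMCConfig",
    "run_mcmc",
    "bgr_diagnostic",
    "split_rhat",
    "autocorrelation",
    "dic",
    "sensitivity_run",
    "SensitivityResult",
]

_TARGET_ACCEPT = 0.44  # scalar random-walk optimum
_BLOCKS = ("alpha", "b", "log_delta", "ush", "ssh", "bind", "bspat",
           "gamma", "ximp")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout and proposal settings.

    Defaults follow the study protocol: two parallel chains, 50,000
    burn-in and 50,000 sampling iterations keeping every 10th, for 10,000
    retained draws in total.  Tests and the reproduction scripts pass
    reduced settings.
    """

    n_chains: int = 2
    burn_in: int = 50_000
    iterations: int = 50_000
    thin: int = 10
    seed: int = 0
    seeds: tuple[int, ...] | None = None
    initial_steps: dict = field(default_factory=lambda: {
        "alpha": 0.1, "b": 0.01, "log_delta": 0.15, "ush": 0.1, "ssh": 0.1,
        "bind": 0.1, "bspat": 0.1, "gamma": 0.1, "ximp": 0.05,
    })
    adapt: bool = True
    overdispersed_starts: bool = True

    def __post_init__(self):
        if self.n_chains < 1 or self.thin < 1 or self.iterations < self.thin:
            raise ValueError("invalid chain layout")
        if self.iterations % self.thin:
            raise ValueError("iterations must be a multiple of thin")

    @property
    def n_keep(self) -> int:
        return self.iterations // self.thin

    def chain_seeds(self) -> tuple[int, ...]:
        if self.seeds is not None:
            if len(self.seeds) != self.n_chains:
                raise ValueError("need one seed per chain")
            return tuple(self.seeds)
        root = np.random.SeedSequence(self.seed)
        return tuple(int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in root.spawn(self.n_chains))


def _log1pexp(x: float) -> float:
    if x > 33.0:
        return x
    if x < -33.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


def run_mcmc(
    data: SCMData,
    priors: SCMPriors = SCMPriors(),
    config: MCMCConfig = MCMCConfig(),
    structure: ModelStructure = ModelStructure(),
) -> PosteriorSamples:
    """Draw from the SCM posterior; identical data + seeds give identical output."""
    if data.missing_covariate and not data.imputation_priors:
        raise ValueError(
            "data has missing covariates without imputation priors; "
            "call impute_missing() first"
        )
    N, K = data.n_regions, data.n_covariates
    C = config
    seeds = C.chain_seeds()
    keep = C.n_keep

    raw = {
        "alpha": np.empty((C.n_chains, keep, 2)),
        "b": np.empty((C.n_chains, keep, 2, K)),
        "log_delta": np.empty((C.n_chains, keep)),
        "ush": np.empty((C.n_chains, keep, N)),
        "ssh": np.empty((C.n_chains, keep, N)),
        "bind": np.empty((C.n_chains, keep, 2, N)),
        "bspat": np.empty((C.n_chains, keep, 2, N)),
        "gamma_contrast": np.empty((C.n_chains, keep, N)),
        "tau_ssh": np.empty((C.n_chains, keep)),
        "tau_ush": np.empty((C.n_chains, keep)),
        "tau_gamma": np.empty((C.n_chains, keep)),
        "tau_bspat": np.empty((C.n_chains, keep, 2)),
        "tau_bind": np.empty((C.n_chains, keep, 2)),
    }
    imp_index = sorted(data.imputation_priors)
    if imp_index:
        raw["x_imputed"] = np.empty((C.n_chains, keep, len(imp_index)))
    derived = {
        "eta1": np.empty((C.n_chains, keep)),
        "eta2": np.empty((C.n_chains, keep)),
        "delta": np.empty((C.n_chains, keep)),
        "delta_sq": np.empty((C.n_chains, keep)),
        "deviance": np.empty((C.n_chains, keep)),
        "sigma_str": np.empty((C.n_chains, keep)),
        "sigma_unstr": np.empty((C.n_chains, keep)),
        "sigma_ind": np.empty((C.n_chains, keep, 2)),
        "sigma_spat": np.empty((C.n_chains, keep, 2)),
        "eta_cells": np.empty((C.n_chains, keep, 2, N)),
        "logit_p": np.empty((C.n_chains, keep, 2, N)),
    }
    meta = {"seeds": seeds, "config": C, "priors": priors,
            "structure": structure, "acceptance": [], "warnings": [],
            "x_imputed_index": imp_index}

    for c in range(C.n_chains):
        _run_chain(data, priors, C, structure, seeds[c], c, raw, derived, meta)

    samples = PosteriorSamples(
        data.region_map, data.covariate_names, raw, derived, meta
    )
    for c, rates in enumerate(meta["acceptance"]):
        for block, rate in rates.items():
            if rate is not None and not (0.05 < rate < 0.95):
                msg = (f"chain {c}: acceptance rate {rate:.2f} for block "
                       f"{block!r} outside (0.05, 0.95)")
                meta["warnings"].append(msg)
                warnings.warn(msg, stacklevel=2)
    return samples


def _run_chain(data, priors, C, structure, seed, c, raw, derived, meta):
    rng = np.random.default_rng(seed)
    N, K = data.n_regions, data.n_covariates
    rmap = data.region_map
    O = data.O.tolist()
    n = data.n.tolist()
    # covariates are centered per (gender, covariate) inside the sampler to
    # decorrelate intercepts from coefficients; the intercept is mapped back
    # to the raw parameterization at record time (b is unaffected)
    xs_raw = data.x * data.covariate_scale
    xbar = np.nanmean(xs_raw, axis=1)  # (2, K)
    xs = (xs_raw - xbar[:, None, :]).tolist()  # mutated by imputation
    edges = [(rmap.index[a], rmap.index[b]) for a, b in sorted(rmap.edges)]
    nbrs = [list(map(int, v)) for v in rmap.neighbor_index_lists()]
    dof_car = N - rmap.n_components
    shape, rate = priors.precision_shape, priors.precision_rate
    ld_var = priors.log_delta_variance
    lgconst = float(np.sum(  # binomial coefficients, fixed given the data
        _gammaln_arr(data.n + 1) - _gammaln_arr(data.O + 1)
        - _gammaln_arr(data.n - data.O + 1)
    ))
    imp_index = meta["x_imputed_index"]
    imp_priors = [data.imputation_priors[idx] for idx in imp_index]

    # --- starting state (overdispersed across chains) ------------------
    spread = (1.0 + 2.0 * c) if C.overdispersed_starts else 1.0
    alpha = []
    for j in range(2):
        tot_n, tot_o = sum(n[j]), sum(O[j])
        pool = (tot_o + 0.5) / (tot_n + 1.0) if tot_n > 0 else 0.5
        alpha.append(math.log(pool / (1 - pool)) + rng.normal() * 0.2 * spread)
    b = [[rng.normal() * 0.002 * spread for _ in range(K)] for _ in range(2)]
    ld = max(-1.5, min(1.5, rng.normal() * 0.2 * spread))
    d = math.exp(ld)

    def centered(scale):
        v = rng.normal(0.0, scale, N)
        return (v - v.mean()).tolist()

    ush = centered(0.03 * spread) if structure.shared else [0.0] * N
    ssh = centered(0.03 * spread) if structure.shared else [0.0] * N
    bind = [centered(0.03 * spread) if structure.specific else [0.0] * N
            for _ in range(2)]
    bspat = [centered(0.03 * spread) if structure.specific else [0.0] * N
             for _ in range(2)]
    gamma = centered(0.03 * spread) if structure.contrast else [0.0] * N
    tau = {"ssh": 10.0 / spread, "ush": 10.0 / spread, "gamma": 10.0 / spread,
           "bspat": [10.0 / spread] * 2, "bind": [10.0 / spread] * 2}
    ximp = [data.x[idx] * data.covariate_scale for idx in imp_index]
    if not structure.covariates:
        b = [[0.0] * K for _ in range(2)]

    def recompute_u():
        u = [[0.0] * N for _ in range(2)]
        for i in range(N):
            phi_i = ush[i] + ssh[i]
            base0 = alpha[0] + sum(b[0][k] * xs[0][i][k] for k in range(K))
            base1 = alpha[1] + sum(b[1][k] * xs[1][i][k] for k in range(K))
            u[0][i] = base0 + d * phi_i + bind[0][i] + bspat[0][i]
            u[1][i] = base1 + phi_i / d + gamma[i] + bind[1][i] + bspat[1][i]
        return u

    u = recompute_u()

    def cell_ll(j, i, uji):
        return O[j][i] * uji - n[j][i] * _log1pexp(uji)

    start_ll = sum(cell_ll(j, i, u[j][i]) for j in range(2) for i in range(N))
    if not math.isfinite(start_ll):
        raise FloatingPointError("non-finite posterior at the starting state")

    steps = dict(C.initial_steps)
    acc = {k: 0 for k in _BLOCKS}
    prop = {k: 0 for k in _BLOCKS}
    acc_post = {k: 0 for k in _BLOCKS}
    prop_post = {k: 0 for k in _BLOCKS}

    def mh(block, logratio):
        prop[block] += 1
        if logratio >= 0.0 or rng.random() < math.exp(logratio):
            acc[block] += 1
            return True
        return False

    total = C.burn_in + C.iterations
    kept = 0
    for t in range(total):
        # --- intercepts and coefficients (flat priors) -----------------
        for j in range(2):
            da = rng.normal() * steps["alpha"]
            dll = 0.0
            for i in range(N):
                dll += cell_ll(j, i, u[j][i] + da) - cell_ll(j, i, u[j][i])
            if mh("alpha", dll):
                alpha[j] += da
                row = u[j]
                for i in range(N):
                    row[i] += da
        if structure.covariates:
            for j in range(2):
                for k in range(K):
                    db = rng.normal() * steps["b"]
                    dll = 0.0
                    for i in range(N):
                        du = db * xs[j][i][k]
                        dll += cell_ll(j, i, u[j][i] + du) - cell_ll(j, i, u[j][i])
                    if mh("b", dll):
                        b[j][k] += db
                        row = u[j]
                        for i in range(N):
                            row[i] += db * xs[j][i][k]

        # --- shared weight ---------------------------------------------
        if structure.shared:
            dld = rng.normal() * steps["log_delta"]
            ld_new = ld + dld
            d_new = math.exp(ld_new)
            dll = (ld * ld - ld_new * ld_new) / (2.0 * ld_var)
            u0_new, u1_new = [0.0] * N, [0.0] * N
            for i in range(N):
                phi_i = ush[i] + ssh[i]
                u0_new[i] = u[0][i] + (d_new - d) * phi_i
                u1_new[i] = u[1][i] + (1.0 / d_new - 1.0 / d) * phi_i
                dll += (cell_ll(0, i, u0_new[i]) - cell_ll(0, i, u[0][i])
                        + cell_ll(1, i, u1_new[i]) - cell_ll(1, i, u[1][i]))
            if mh("log_delta", dll):
                ld, d = ld_new, d_new
                u[0], u[1] = u0_new, u1_new

            # --- shared surface sites ----------------------------------
            for i in range(N):
                dv = rng.normal() * steps["ush"]
                v_old = ush[i]
                v_new = v_old + dv
                dlp = -0.5 * tau["ush"] * (v_new * v_new - v_old * v_old)
                du0, du1 = d * dv, dv / d
                dlp += (cell_ll(0, i, u[0][i] + du0) - cell_ll(0, i, u[0][i])
                        + cell_ll(1, i, u[1][i] + du1) - cell_ll(1, i, u[1][i]))
                if mh("ush", dlp):
                    ush[i] = v_new
                    u[0][i] += du0
                    u[1][i] += du1
            for i in range(N):
                dv = rng.normal() * steps["ssh"]
                v_old = ssh[i]
                v_new = v_old + dv
                dq = 0.0
                for l in nbrs[i]:
                    dq += (v_new - ssh[l]) ** 2 - (v_old - ssh[l]) ** 2
                dlp = -0.5 * tau["ssh"] * dq
                du0, du1 = d * dv, dv / d
                dlp += (cell_ll(0, i, u[0][i] + du0) - cell_ll(0, i, u[0][i])
                        + cell_ll(1, i, u[1][i] + du1) - cell_ll(1, i, u[1][i]))
                if mh("ssh", dlp):
                    ssh[i] = v_new
                    u[0][i] += du0
                    u[1][i] += du1

        # --- gender-specific surfaces ----------------------------------
        if structure.specific:
            for j in range(2):
                bj = bind[j]
                for i in range(N):
                    dv = rng.normal() * steps["bind"]
                    v_new = bj[i] + dv
                    dlp = -0.5 * tau["bind"][j] * (v_new * v_new - bj[i] * bj[i])
                    dlp += cell_ll(j, i, u[j][i] + dv) - cell_ll(j, i, u[j][i])
                    if mh("bind", dlp):
                        bj[i] = v_new
                        u[j][i] += dv
            for j in range(2):
                sj = bspat[j]
                for i in range(N):
                    dv = rng.normal() * steps["bspat"]
                    v_old = sj[i]
                    v_new = v_old + dv
                    dq = 0.0
                    for l in nbrs[i]:
                        dq += (v_new - sj[l]) ** 2 - (v_old - sj[l]) ** 2
                    dlp = -0.5 * tau["bspat"][j] * dq
                    dlp += cell_ll(j, i, u[j][i] + dv) - cell_ll(j, i, u[j][i])
                    if mh("bspat", dlp):
                        sj[i] = v_new
                        u[j][i] += dv

        # --- gender-contrast surface -----------------------------------
        if structure.contrast:
            for i in range(N):
                dv = rng.normal() * steps["gamma"]
                v_old = gamma[i]
                v_new = v_old + dv
                dq = 0.0
                for l in nbrs[i]:
                    dq += (v_new - gamma[l]) ** 2 - (v_old - gamma[l]) ** 2
                dlp = -0.5 * tau["gamma"] * dq
                dlp += cell_ll(1, i, u[1][i] + dv) - cell_ll(1, i, u[1][i])
                if mh("gamma", dlp):
                    gamma[i] = v_new
                    u[1][i] += dv

        # --- imputed covariates ----------------------------------------
        for m, (j, i, k) in enumerate(imp_index):
            pm, pv = imp_priors[m]
            x_old = ximp[m]
            dx = rng.normal() * steps["ximp"] * data.covariate_scale
            x_new = x_old + dx
            z_old = x_old / data.covariate_scale - pm
            z_new = x_new / data.covariate_scale - pm
            dlp = -(z_new * z_new - z_old * z_old) / (2.0 * pv)
            du = b[j][k] * dx
            dlp += cell_ll(j, i, u[j][i] + du) - cell_ll(j, i, u[j][i])
            if mh("ximp", dlp):
                ximp[m] = x_new
                xs[j][i][k] = x_new - xbar[j][k]
                u[j][i] += du

        # --- precision Gibbs updates -----------------------------------
        if structure.shared:
            q = sum((ssh[a] - ssh[bb]) ** 2 for a, bb in edges)
            tau["ssh"] = rng.gamma(shape + 0.5 * dof_car, 1.0 / (rate + 0.5 * q))
            s2 = sum(v * v for v in ush)
            tau["ush"] = rng.gamma(shape + 0.5 * N, 1.0 / (rate + 0.5 * s2))
        if structure.specific:
            for j in range(2):
                q = sum((bspat[j][a] - bspat[j][bb]) ** 2 for a, bb in edges)
                tau["bspat"][j] = rng.gamma(shape + 0.5 * dof_car,
                                            1.0 / (rate + 0.5 * q))
                s2 = sum(v * v for v in bind[j])
                tau["bind"][j] = rng.gamma(shape + 0.5 * N,
                                           1.0 / (rate + 0.5 * s2))
        if structure.contrast:
            q = sum((gamma[a] - gamma[bb]) ** 2 for a, bb in edges)
            tau["gamma"] = rng.gamma(shape + 0.5 * dof_car,
                                     1.0 / (rate + 0.5 * q))

        # --- sum-to-zero recentring (intercepts absorb the level) ------
        if structure.shared:
            for comp in (ush, ssh):
                m = sum(comp) / N
                for i in range(N):
                    comp[i] -= m
                alpha[0] += d * m
                alpha[1] += m / d
        if structure.specific:
            for j in range(2):
                for comp in (bind[j], bspat[j]):
                    m = sum(comp) / N
                    for i in range(N):
                        comp[i] -= m
                    alpha[j] += m
        if structure.contrast:
            m = sum(gamma) / N
            for i in range(N):
                gamma[i] -= m
            alpha[1] += m

        # --- adaptation (burn-in only) ---------------------------------
        if C.adapt and t < C.burn_in and (t + 1) % 50 == 0:
            batch = (t + 1) // 50
            gain = min(1.0, 4.0 / math.sqrt(batch))
            for block in _BLOCKS:
                if prop[block]:
                    r = acc[block] / prop[block]
                    steps[block] *= math.exp(gain * (r - _TARGET_ACCEPT))
                    acc[block] = prop[block] = 0
        if t == C.burn_in - 1:
            for block in _BLOCKS:
                acc[block] = prop[block] = 0
        if (t + 1) % 200 == 0:
            u = recompute_u()  # cancel incremental floating drift

        # --- record -----------------------------------------------------
        if t >= C.burn_in and (t - C.burn_in + 1) % C.thin == 0:
            alpha_raw = [alpha[j] - sum(b[j][k] * xbar[j][k] for k in range(K))
                         for j in range(2)]
            _record(raw, derived, c, kept, alpha_raw, b, ld, ush, ssh, bind,
                    bspat, gamma, tau, ximp, u, lgconst, O, n, N, K)
            kept += 1

    rates = {}
    for block in _BLOCKS:
        rates[block] = acc[block] / prop[block] if prop[block] else None
    meta["acceptance"].append(rates)


def _gammaln_arr(a):
    from scipy.special import gammaln
    return gammaln(a)


def _record(raw, derived, c, kk, alpha, b, ld, ush, ssh, bind, bspat, gamma,
            tau, ximp, u, lgconst, O, n, N, K):
    d = math.exp(ld)
    raw["alpha"][c, kk] = alpha
    raw["b"][c, kk] = b
    raw["log_delta"][c, kk] = ld
    raw["ush"][c, kk] = ush
    raw["ssh"][c, kk] = ssh
    raw["bind"][c, kk] = bind
    raw["bspat"][c, kk] = bspat
    raw["gamma_contrast"][c, kk] = gamma
    raw["tau_ssh"][c, kk] = tau["ssh"]
    raw["tau_ush"][c, kk] = tau["ush"]
    raw["tau_gamma"][c, kk] = tau["gamma"]
    raw["tau_bspat"][c, kk] = tau["bspat"]
    raw["tau_bind"][c, kk] = tau["bind"]
    if "x_imputed" in raw:
        raw["x_imputed"][c, kk] = ximp
    phi = np.asarray(ush) + np.asarray(ssh)
    ups = np.asarray(bind) + np.asarray(bspat)
    gam = np.asarray(gamma)
    eta = np.stack([d * phi + ups[0], phi / d + gam + ups[1]])
    derived["eta_cells"][c, kk] = eta
    derived["logit_p"][c, kk] = u
    num1 = float(np.var(d * phi))
    den1 = num1 + float(np.var(ups[0]))
    num2 = float(np.var(phi / d))
    den2 = num2 + float(np.var(gam)) + float(np.var(ups[1]))
    derived["eta1"][c, kk] = num1 / den1 if den1 > 0 else 0.0
    derived["eta2"][c, kk] = num2 / den2 if den2 > 0 else 0.0
    derived["delta"][c, kk] = d
    derived["delta_sq"][c, kk] = d * d
    sd = lambda v: float(np.std(np.asarray(v), ddof=1))
    derived["sigma_str"][c, kk] = sd(ssh)
    derived["sigma_unstr"][c, kk] = sd(ush)
    derived["sigma_ind"][c, kk] = [sd(bind[0]), sd(bind[1])]
    derived["sigma_spat"][c, kk] = [sd(bspat[0]), sd(bspat[1])]
    ll = lgconst
    for j in range(2):
        for i in range(N):
            ll += O[j][i] * u[j][i] - n[j][i] * _log1pexp(u[j][i])
    derived["deviance"][c, kk] = -2.0 * ll


# ---------------------------------------------------------------------------
# Diagnostics

def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_draws); each chain is halved before the
    between/within variance comparison.  A degenerate (constant) trace
    returns 1.0 with a warning.
    """
    import arviz as az

    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("split_rhat needs >= 2 chains of equal length")
    if np.allclose(arr.var(), 0.0):
        warnings.warn("degenerate (constant) chains; R-hat reported as 1",
                      stacklevel=2)
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = float(np.asarray(az.rhat(az.convert_to_dataset(arr))["x"]))
    return 1.0 if math.isnan(val) else val


def bgr_diagnostic(
    samples: PosteriorSamples | np.ndarray, parameters=None
) -> pd.Series:
    """Split R-hat per selected parameter (values near 1 mean convergence)."""
    if isinstance(samples, np.ndarray):
        return pd.Series({"x": split_rhat(samples)})
    if samples.n_chains < 2:
        raise ValueError(
            "R-hat needs >= 2 chains; increase MCMCConfig.n_chains"
        )
    series = samples.scalar_series()
    if parameters is None:
        parameters = list(series)
    out = {}
    for name in parameters:
        if name not in series:
            raise KeyError(f"unknown parameter {name!r}")
        out[name] = split_rhat(series[name])
    return pd.Series(out, name="rhat")


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag, normalized to acf(0)=1."""
    from statsmodels.tsa.stattools import acf

    x = np.asarray(series, dtype=float).ravel()
    if x.size <= max_lag:
        raise ValueError("series shorter than max_lag")
    if np.allclose(x.var(), 0.0):
        warnings.warn("zero-variance series; autocorrelation undefined",
                      stacklevel=2)
        return np.concatenate([[1.0], np.full(max_lag, np.nan)])
    return acf(x, nlags=max_lag, fft=True)


def dic(samples: PosteriorSamples, data: SCMData) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    ``pD = mean deviance - deviance at the plug-in``, with the plug-in taken
    at the posterior mean of the cellwise linear predictor; ``DIC = mean
    deviance + pD``.  A negative pD is possible for pathological fits and
    triggers a warning rather than an error.
    """
    dev = samples.stacked("deviance")
    bad = np.flatnonzero(~np.isfinite(dev))
    if bad.size:
        raise FloatingPointError(f"non-finite deviance at draws {bad[:10].tolist()}")
    dbar = float(dev.mean())
    ubar = samples.stacked("logit_p").mean(axis=0)
    from scipy.special import gammaln
    const = float(np.sum(gammaln(data.n + 1) - gammaln(data.O + 1)
                         - gammaln(data.n - data.O + 1)))
    ll_hat = const + float(np.sum(data.O * ubar - data.n * np.logaddexp(0.0, ubar)))
    dhat = -2.0 * ll_hat
    pd_ = dbar - dhat
    if pd_ < 0:
        warnings.warn(f"negative pD ({pd_:.3f}); plug-in DIC can misbehave",
                      stacklevel=2)
    return dbar + pd_, pd_


# ---------------------------------------------------------------------------
# Sensitivity harness

@dataclass
class SensitivityResult:
    """Side-by-side posterior summaries per (prior, exclusion) setting."""

    table: pd.DataFrame
    densities: dict
    samples: dict


def sensitivity_run(
    data: SCMData,
    priors_list: list[SCMPriors],
    config: MCMCConfig,
    exclusions: list[str] | None = None,
    structure: ModelStructure = ModelStructure(),
    density_grid: int = 128,
) -> SensitivityResult:
    """Refit the model under alternative precision priors and region exclusions.

    One run per (prior, exclusion) combination, with ``None`` standing for
    the full region set.  Seeds come from the config alone, so repeating a
    setting reproduces its rows exactly.  Densities (Gaussian KDE) of each
    covariate RR are exported for the kernel-density robustness display.
    """
    from scipy.stats import gaussian_kde

    if not priors_list:
        raise ValueError("need at least one prior setting")
    settings = [(p, e) for p in priors_list
                for e in [None] + list(exclusions or [])]
    rows, densities, all_samples = [], {}, {}
    for idx, (pri, excl) in enumerate(settings):
        d_run = data.drop_region(excl) if excl else data
        d_run = impute_missing(d_run) if d_run.missing_covariate else d_run
        samples = run_mcmc(d_run, pri, config, structure)
        label = pri.name + (f"-excl_{excl}" if excl else "")
        all_samples[label] = samples
        dic_val, pd_val = dic(samples, d_run)
        row = {"setting": label, "priors": pri.name,
               "excluded": excl or "", "DIC": dic_val, "pD": pd_val}
        for gender in GENDERS:
            for name in data.covariate_names:
                mean, lo, hi = covariate_rr(samples, name, gender)
                row[f"rr_{name}_{gender}"] = mean
                row[f"rr_{name}_{gender}_lo"] = lo
                row[f"rr_{name}_{gender}_hi"] = hi
                j = GENDERS.index(gender)
                k = samples.covariate_names.index(name)
                draws = np.exp(samples.stacked("b")[:, j, k])
                if np.std(draws) > 0:
                    kde = gaussian_kde(draws)
                    grid = np.linspace(draws.min(), draws.max(), density_grid)
                    densities[(label, f"rr_{name}_{gender}")] = (
                        grid, kde(grid)
                    )
        for key, short in [("eta1", "eta_male"), ("eta2", "eta_female"),
                           ("delta", "delta")]:
            flat = samples.stacked(key)
            row[short] = float(flat.mean())
            row[f"{short}_lo"] = float(np.quantile(flat, 0.025))
            row[f"{short}_hi"] = float(np.quantile(flat, 0.975))
        rows.append(row)
    return SensitivityResult(pd.DataFrame(rows), densities, all_samples)
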