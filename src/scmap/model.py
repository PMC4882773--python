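"""The extended shared component model (SCM) for two-group spatial prevalence.

The model joins two binomial prevalence surfaces (here: male and female
hypertension across regions) through a shared spatial risk component:

.. math::

    O_{ji} \\sim \\mathrm{Bin}(n_{ji}, p_{ji}), \\qquad
    \\mathrm{logit}(p_{ji}) = \\alpha_j + b_j^\\top x_{ji} + \\eta_{ji}

with ``eta_1i = delta * phi_i + upsilon_1i`` and
``eta_2i = phi_i / delta + gamma_i + upsilon_2i``.  The shared surface
``phi`` and the group-specific surfaces ``upsilon_j`` carry convolution
(BYM) priors — a spatially structured intrinsic-CAR part plus an
unstructured i.i.d. normal part — while ``gamma`` (the group-contrast
surface) is intrinsic CAR.  The log of the shared weight ``delta`` is
normal with mean zero, so the two group loadings ``delta`` and
``1/delta`` multiply to one exactly, which identifies the weight.  All
precisions carry gamma priors.

Because the outcome is non-rare, the likelihood is binomial rather than
the Poisson form classical shared component disease mapping uses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .regions import GENDERS, RegionMap, car_quadratic_form

__all__ = [
    "SCMData",
    "SCMParams",
    "SCMPriors",
    "ModelStructure",
    "PRIORS_1",
    "PRIORS_2",
    "PRIORS_3",
    "PosteriorSamples",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "variance_fractions",
    "component_sds",
    "covariate_rr",
    "impute_missing",
]

#: Default regional covariates (proportions emitted by descriptive aggregation).
DEFAULT_COVARIATES = ("prop_elderly", "prop_obese", "prop_apple")


@dataclass(frozen=True)
class SCMPriors:
    """Hyperprior settings: one gamma prior shared by every precision,
    and the variance of the zero-mean normal prior on log(delta)."""

    precision_shape: float = 1.0
    precision_rate: float = 1.0e-4
    log_delta_variance: float = 0.169
    name: str = "priors"

    def __post_init__(self):
        if min(self.precision_shape, self.precision_rate,
               self.log_delta_variance) <= 0:
            raise ValueError("prior hyperparameters must be positive")


PRIORS_1 = SCMPriors(1.0, 1.0e-4, name="priors1")
PRIORS_2 = SCMPriors(1000.0, 5.0e-7, name="priors2")
PRIORS_3 = SCMPriors(5.0, 5.0e-5, name="priors3")


@dataclass(frozen=True)
class ModelStructure:
    """Which random-effect blocks the model includes (all on by default).

    Turning blocks off yields the nested reductions used for closed-form
    sampler checks (e.g. intercept-only binomial)."""

    shared: bool = True
    specific: bool = True
    contrast: bool = True
    covariates: bool = True


@dataclass
class SCMData:
    """Per-(gender, region) counts, denominators and regional covariates.

    Arrays are indexed ``[gender, region(, covariate)]`` in the order of
    ``region_map.regions`` with gender 0 = male, 1 = female.  ``x`` holds
    raw proportions in [0, 1]; ``covariate_scale`` (default 100, i.e.
    percentage points) multiplies them on entry to the linear predictor so
    coefficients read per percentage point.
    """

    region_map: RegionMap
    O: np.ndarray
    n: np.ndarray
    x: np.ndarray
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    covariate_scale: float = 100.0
    substituted_regions: frozenset[str] = frozenset()
    imputation_priors: dict[tuple[int, int, int], tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        N, K = self.region_map.n_regions, len(self.covariate_names)
        self.O = np.asarray(self.O, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.O.shape != (2, N) or self.n.shape != (2, N):
            raise ValueError(f"O and n must have shape (2, {N})")
        if self.x.shape != (2, N, K):
            raise ValueError(f"x must have shape (2, {N}, {K})")
        if np.any(self.O < 0) or np.any(self.n < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.O > self.n):
            bad = np.argwhere(self.O > self.n)
            raise ValueError(f"cases exceed denominators at (gender, region) {bad.tolist()}")
        finite = np.isfinite(self.x)
        if np.any((self.x[finite] < 0) | (self.x[finite] > 1)):
            raise ValueError("covariates must be proportions in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.region_map.n_regions

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def missing_covariate(self) -> set[tuple[int, int, int]]:
        return {tuple(idx) for idx in np.argwhere(~np.isfinite(self.x))}

    def scaled_x(self) -> np.ndarray:
        return self.x * self.covariate_scale

    @classmethod
    def from_regional_table(
        cls,
        df: pd.DataFrame,
        region_map: RegionMap,
        covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
        covariate_scale: float = 100.0,
        substituted_regions=(),
    ) -> "SCMData":
        """Build from the long regional table (region, gender, cases, n, covars)."""
        N, K = region_map.n_regions, len(covariate_names)
        O = np.full((2, N), np.nan)
        n = np.full((2, N), np.nan)
        x = np.full((2, N, K), np.nan)
        for _, row in df.iterrows():
            region = str(row["region"])
            if region not in region_map.index:
                raise ValueError(f"row references unknown region {region!r}")
            i = region_map.index[region]
            j = GENDERS.index(row["gender"])
            O[j, i] = row["cases"]
            n[j, i] = row["n"]
            for k, name in enumerate(covariate_names):
                if name in row.index:
                    x[j, i, k] = row[name]
        if np.isnan(O).any() or np.isnan(n).any():
            missing = [
                (GENDERS[j], region_map.regions[i])
                for j, i in np.argwhere(np.isnan(O))
            ]
            raise ValueError(f"regional table lacks rows for cells {missing}")
        return cls(region_map, O, n, x, covariate_names, covariate_scale,
                   frozenset(substituted_regions))

    def to_regional_table(self) -> pd.DataFrame:
        rows = []
        for j, gender in enumerate(GENDERS):
            for i, region in enumerate(self.region_map.regions):
                row = {"region": region, "gender": gender,
                       "cases": int(self.O[j, i]), "n": int(self.n[j, i])}
                for k, name in enumerate(self.covariate_names):
                    row[name] = self.x[j, i, k]
                rows.append(row)
        return pd.DataFrame(rows)

    def drop_region(self, region: str) -> "SCMData":
        """Remove one region from counts, covariates and all CAR structures."""
        if region not in self.region_map.index:
            raise ValueError(f"unknown region {region!r}")
        i = self.region_map.index[region]
        keep = [k for k in range(self.n_regions) if k != i]
        return SCMData(
            self.region_map.drop([region]),
            self.O[:, keep], self.n[:, keep], self.x[:, keep, :],
            self.covariate_names, self.covariate_scale,
            self.substituted_regions - {region},
        )


@dataclass
class SCMParams:
    """One full parameter state of the extended SCM.

    ``alpha`` are the gender intercepts (log-odds), ``b`` the gender-specific
    regional-covariate coefficients (log-odds per scaled covariate unit),
    ``log_delta`` the log shared weight.  ``ush``/``ssh`` are the
    unstructured/structured halves of the shared surface, ``bind``/``bspat``
    those of the gender-specific surfaces, and ``gamma_contrast`` the
    CAR-distributed gender-contrast surface.  All region-indexed components
    are kept sum-to-zero; the intercepts absorb their levels.
    """

    alpha: np.ndarray
    b: np.ndarray
    log_delta: float
    ush: np.ndarray
    ssh: np.ndarray
    bind: np.ndarray
    bspat: np.ndarray
    gamma_contrast: np.ndarray
    tau_ssh: float = 1.0
    tau_ush: float = 1.0
    tau_gamma: float = 1.0
    tau_bspat: np.ndarray = None
    tau_bind: np.ndarray = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        for name in ("ush", "ssh", "gamma_contrast"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("bind", "bspat"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.tau_bspat is None:
            self.tau_bspat = np.ones(2)
        if self.tau_bind is None:
            self.tau_bind = np.ones(2)
        self.tau_bspat = np.asarray(self.tau_bspat, dtype=float)
        self.tau_bind = np.asarray(self.tau_bind, dtype=float)
        if min(self.tau_ssh, self.tau_ush, self.tau_gamma,
               self.tau_bspat.min(), self.tau_bind.min()) <= 0:
            raise ValueError("all precisions must be positive")

    @property
    def delta(self) -> float:
        return math.exp(self.log_delta)

    @property
    def weights(self) -> tuple[float, float]:
        """Per-gender shared-component loadings (delta, 1/delta); product is 1."""
        d = self.delta
        return d, 1.0 / d

    @property
    def phi(self) -> np.ndarray:
        """Shared surface, convolution of unstructured and structured halves."""
        return self.ush + self.ssh

    @property
    def upsilon(self) -> np.ndarray:
        """Gender-specific surfaces (2, N)."""
        return self.bind + self.bspat

    def eta(self) -> np.ndarray:
        """Spatial log-odds offsets per (gender, region)."""
        d = self.delta
        phi = self.phi
        ups = self.upsilon
        return np.stack([d * phi + ups[0],
                         phi / d + self.gamma_contrast + ups[1]])

    @classmethod
    def zeros(cls, n_regions: int, n_covariates: int) -> "SCMParams":
        z = np.zeros(n_regions)
        return cls(
            alpha=np.zeros(2), b=np.zeros((2, n_covariates)), log_delta=0.0,
            ush=z.copy(), ssh=z.copy(), bind=np.zeros((2, n_regions)),
            bspat=np.zeros((2, n_regions)), gamma_contrast=z.copy(),
        )


def _check_finite(params: SCMParams) -> None:
    for name in ("alpha", "b", "ush", "ssh", "bind", "bspat", "gamma_contrast"):
        if not np.all(np.isfinite(getattr(params, name))):
            raise FloatingPointError(f"non-finite values in {name}")
    if not math.isfinite(params.log_delta):
        raise FloatingPointError("non-finite log_delta")


def linear_predictor(
    params: SCMParams, data: SCMData, x: np.ndarray | None = None
) -> np.ndarray:
    """Fitted probabilities per (gender, region), strictly inside (0, 1).

    ``x`` optionally overrides the data's covariates (raw-proportion scale),
    e.g. with within-MCMC imputations filled in; by this point no missing
    entries may remain.
    """
    _check_finite(params)
    xs = (data.x if x is None else np.asarray(x, dtype=float)) * data.covariate_scale
    if not np.all(np.isfinite(xs)):
        raise ValueError(
            "covariates contain missing values; run impute_missing first"
        )
    u = logit_cells(params, data, xs)
    return expit(u)


def logit_cells(params: SCMParams, data: SCMData, xs: np.ndarray) -> np.ndarray:
    """Linear predictor on the log-odds scale (xs already scaled)."""
    fixed = params.alpha[:, None] + np.einsum("jk,jik->ji", params.b, xs)
    return fixed + params.eta()


def log_likelihood(
    params: SCMParams, data: SCMData, x: np.ndarray | None = None
) -> float:
    """Binomial log likelihood ``sum log Bin(O | n, p)`` including constants."""
    xs = (data.x if x is None else np.asarray(x, dtype=float)) * data.covariate_scale
    u = logit_cells(params, data, xs)
    O, n = data.O, data.n
    const = gammaln(n + 1) - gammaln(O + 1) - gammaln(n - O + 1)
    # O*log p + (n-O)*log(1-p) written on the logit scale for stability
    ll = const + O * u - n * np.logaddexp(0.0, u)
    return float(ll.sum())


def _gamma_logpdf(tau: float, shape: float, rate: float) -> float:
    return (shape * math.log(rate) - math.lgamma(shape)
            + (shape - 1.0) * math.log(tau) - rate * tau)


def _normal_logpdf(v: float, var: float) -> float:
    return -0.5 * (math.log(2.0 * math.pi * var) + v * v / var)


def _car_logdensity(values: np.ndarray, tau: float, rmap: RegionMap) -> float:
    """Intrinsic-CAR log density: ((N-C)/2) log(tau/2pi) - (tau/2) Q."""
    q = car_quadratic_form(values, rmap)
    dof = rmap.n_regions - rmap.n_components
    return 0.5 * dof * math.log(tau / (2.0 * math.pi)) - 0.5 * tau * q


def _iid_logdensity(values: np.ndarray, tau: float) -> float:
    N = values.size
    return 0.5 * N * math.log(tau / (2.0 * math.pi)) - 0.5 * tau * float(
        np.sum(values ** 2)
    )


def log_prior(
    params: SCMParams,
    priors: SCMPriors,
    rmap: RegionMap,
    structure: ModelStructure = ModelStructure(),
    data: SCMData | None = None,
    x: np.ndarray | None = None,
) -> float:
    """Joint log prior of one state.

    Intrinsic-CAR terms for ``ssh``, each gender's ``bspat`` and
    ``gamma_contrast``; i.i.d. normals for ``ush`` and ``bind``; gamma
    log densities for every active precision; a zero-mean normal for
    ``log_delta``; improper flat (0) contributions for the intercepts and
    coefficients.  When ``data`` carries imputation priors and ``x`` is the
    imputed covariate matrix, the normal imputation terms are included.
    """
    _check_finite(params)
    a, r = priors.precision_shape, priors.precision_rate
    lp = _normal_logpdf(params.log_delta, priors.log_delta_variance)
    if structure.shared:
        lp += _car_logdensity(params.ssh, params.tau_ssh, rmap)
        lp += _iid_logdensity(params.ush, params.tau_ush)
        lp += _gamma_logpdf(params.tau_ssh, a, r)
        lp += _gamma_logpdf(params.tau_ush, a, r)
    if structure.specific:
        for j in range(2):
            lp += _car_logdensity(params.bspat[j], params.tau_bspat[j], rmap)
            lp += _iid_logdensity(params.bind[j], params.tau_bind[j])
            lp += _gamma_logpdf(params.tau_bspat[j], a, r)
            lp += _gamma_logpdf(params.tau_bind[j], a, r)
    if structure.contrast:
        lp += _car_logdensity(params.gamma_contrast, params.tau_gamma, rmap)
        lp += _gamma_logpdf(params.tau_gamma, a, r)
    if data is not None and x is not None and data.imputation_priors:
        for (j, i, k), (m, v) in data.imputation_priors.items():
            lp += _normal_logpdf(float(x[j, i, k]) - m, v)
    return float(lp)


def log_posterior(
    params: SCMParams,
    data: SCMData,
    priors: SCMPriors,
    structure: ModelStructure = ModelStructure(),
    x: np.ndarray | None = None,
) -> float:
    return log_likelihood(params, data, x) + log_prior(
        params, priors, data.region_map, structure, data, x
    )


def variance_fractions(
    params: SCMParams, ddof: int = 0
) -> tuple[float, float]:
    """Shared-variance fractions (eta_1, eta_2) within one state.

    ``eta_1 = var(delta*phi) / (var(delta*phi) + var(upsilon_1))`` and the
    second-group analogue whose denominator additionally carries
    ``var(gamma_contrast)``.  Variances are empirical across regions
    (population convention by default).  Both lie in [0, 1]; an all-zero
    numerator and denominator yields 0 with a degeneracy warning.
    """
    if params.ush.size < 2:
        raise ValueError("variance fractions need at least two regions")
    d = params.delta
    phi = params.phi
    ups = params.upsilon
    out = []
    shared_var = [np.var(d * phi, ddof=ddof), np.var(phi / d, ddof=ddof)]
    extra = [0.0, float(np.var(params.gamma_contrast, ddof=ddof))]
    for j in range(2):
        num = float(shared_var[j])
        den = num + float(np.var(ups[j], ddof=ddof)) + extra[j]
        if den == 0.0:
            warnings.warn(
                "degenerate variance fraction (all components constant); "
                "defining eta = 0", stacklevel=2,
            )
            out.append(0.0)
        else:
            out.append(num / den)
    return out[0], out[1]


def component_sds(params: SCMParams, ddof: int = 1) -> dict[str, float]:
    """Empirical across-region SDs of the random-effect components.

    ``sigma_str``/``sigma_unstr`` for the shared structured/unstructured
    halves, ``sigma_ind``/``sigma_spat`` per gender for the specific halves.
    Sample-SD convention (ddof=1) by default.
    """
    if params.ush.size < 2:
        raise ValueError("component SDs need at least two regions")
    sd = lambda v: float(np.std(v, ddof=ddof))
    return {
        "sigma_str": sd(params.ssh),
        "sigma_unstr": sd(params.ush),
        "sigma_ind_male": sd(params.bind[0]),
        "sigma_ind_female": sd(params.bind[1]),
        "sigma_spat_male": sd(params.bspat[0]),
        "sigma_spat_female": sd(params.bspat[1]),
    }


def impute_missing(data: SCMData) -> SCMData:
    """Apply the substitution and missing-covariate rules prior to fitting.

    For each region marked for substitution, both genders' cases and
    denominators are replaced by the across-region average of the remaining
    regions, rounded to the nearest integer (keeping the binomial likelihood
    well defined).  Each missing covariate entry receives a normal
    imputation prior with the mean and variance (sample convention) of the
    observed entries of the same covariate and gender; the value itself is
    then treated as a parameter and sampled within MCMC rather than fixed.
    """
    O, n, x = data.O.copy(), data.n.copy(), data.x.copy()
    sub_idx = [data.region_map.index[r] for r in data.substituted_regions]
    if sub_idx:
        keep = [i for i in range(data.n_regions) if i not in sub_idx]
        if not keep:
            raise ValueError("cannot substitute every region")
        for j in range(2):
            O_mean = round(float(np.mean(data.O[j, keep])))
            n_mean = round(float(np.mean(data.n[j, keep])))
            for i in sub_idx:
                O[j, i] = O_mean
                n[j, i] = n_mean
    priors: dict[tuple[int, int, int], tuple[float, float]] = {}
    for k in range(data.n_covariates):
        for j in range(2):
            col = data.x[j, :, k]
            obs = col[np.isfinite(col)]
            if obs.size == 0:
                obs = data.x[:, :, k][np.isfinite(data.x[:, :, k])]
            if obs.size == 0:
                raise ValueError(
                    f"covariate {data.covariate_names[k]!r} missing in all regions"
                )
            m = float(np.mean(obs))
            v = float(np.var(obs, ddof=1)) if obs.size > 1 else 1e-4
            v = max(v, 1e-8)
            for i in np.flatnonzero(~np.isfinite(col)):
                priors[(j, int(i), k)] = (m, v)
                x[j, i, k] = m  # initial fill; resampled within MCMC
    return replace(
        data, O=O, n=n, x=x, imputation_priors=priors,
        substituted_regions=data.substituted_regions,
    )


class PosteriorSamples:
    """Thinned multi-chain posterior draws with per-draw derived quantities.

    Raw states are stored as arrays keyed by parameter block with leading
    dimensions ``(chain, draw)``; :meth:`state` reassembles a full
    :class:`SCMParams` for any draw.  ``derived`` carries per-draw
    ``eta1``/``eta2`` (each in [0, 1]), ``delta``, ``delta_sq``, component
    SDs, the cellwise linear predictor and the deviance ``-2 log L``.
    """

    def __init__(self, region_map: RegionMap, covariate_names, raw: dict,
                 derived: dict, meta: dict):
        self.region_map = region_map
        self.covariate_names = tuple(covariate_names)
        self.raw = raw
        self.derived = derived
        self.meta = meta
        lengths = {v.shape[:2] for v in raw.values()}
        if len(lengths) != 1:
            raise ValueError("inconsistent chain/draw dimensions")
        self.n_chains, self.n_draws = lengths.pop()
        if self.n_draws == 0:
            raise ValueError("no retained draws")

    def stacked(self, key: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        source = self.raw if key in self.raw else self.derived
        arr = source[key]
        return arr.reshape((self.n_chains * self.n_draws,) + arr.shape[2:])

    def state(self, chain: int, draw: int) -> SCMParams:
        r = self.raw
        return SCMParams(
            alpha=r["alpha"][chain, draw], b=r["b"][chain, draw],
            log_delta=float(r["log_delta"][chain, draw]),
            ush=r["ush"][chain, draw], ssh=r["ssh"][chain, draw],
            bind=r["bind"][chain, draw], bspat=r["bspat"][chain, draw],
            gamma_contrast=r["gamma_contrast"][chain, draw],
            tau_ssh=float(r["tau_ssh"][chain, draw]),
            tau_ush=float(r["tau_ush"][chain, draw]),
            tau_gamma=float(r["tau_gamma"][chain, draw]),
            tau_bspat=r["tau_bspat"][chain, draw],
            tau_bind=r["tau_bind"][chain, draw],
        )

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Named scalar traces (chain, draw) for diagnostics and summaries."""
        out: dict[str, np.ndarray] = {
            "alpha_male": self.raw["alpha"][:, :, 0],
            "alpha_female": self.raw["alpha"][:, :, 1],
            "log_delta": self.raw["log_delta"],
        }
        for k, name in enumerate(self.covariate_names):
            out[f"b_{name}_male"] = self.raw["b"][:, :, 0, k]
            out[f"b_{name}_female"] = self.raw["b"][:, :, 1, k]
        for key in ("eta1", "eta2", "delta", "delta_sq", "deviance",
                    "sigma_str", "sigma_unstr"):
            out[key] = self.derived[key]
        return out

    def summary(self, rhat: Mapping[str, float] | None = None) -> pd.DataFrame:
        rows = []
        for name, arr in self.scalar_series().items():
            flat = arr.reshape(-1)
            rows.append({
                "parameter": name,
                "mean": float(flat.mean()), "sd": float(flat.std(ddof=1)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q50": float(np.quantile(flat, 0.5)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": (float(rhat[name])
                         if rhat is not None and name in rhat else np.nan),
            })
        return pd.DataFrame(rows)

    def to_long_text(self, path, sep: str = "\t") -> None:
        """Long-format draw export: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self.scalar_series().items():
            c, d = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), d),
                "iteration": np.tile(np.arange(d), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def covariate_rr(
    samples: PosteriorSamples, covariate: str, gender: str, delta_x: float = 1.0
) -> tuple[float, float, float]:
    """Posterior mean and 95 % interval of the covariate relative risk.

    The RR is ``exp(b * delta_x)`` computed draw by draw (so the interval is
    the quantile interval of the exponentiated draws, not an exponentiated
    interval of means).  ``delta_x`` is in scaled covariate units
    (percentage points under the default scale).
    """
    if covariate not in samples.covariate_names:
        raise ValueError(f"unknown covariate {covariate!r}")
    k = samples.covariate_names.index(covariate)
    j = GENDERS.index(gender)
    draws = samples.stacked("b")[:, j, k]
    if draws.size == 0:
        raise ValueError("empty posterior sample")
    rr = np.exp(draws * delta_x)
    return (float(rr.mean()),
            float(np.quantile(rr, 0.025)),
            float(np.quantile(rr, 0.975)))
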