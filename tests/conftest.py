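import numpy as np
import pytest

import scmap
from scmap import SCMData, build_region_map


@pytest.fixture(scope="session")
def zhejiang():
    return scmap.zhejiang_map()


@pytest.fixture
def path_map():
    return build_region_map(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def toy_data(path_map):
    """3-region, 2-gender dataset with two covariates, no missingness."""
    rng = np.random.default_rng(42)
    n = rng.integers(50, 120, size=(2, 3))
    O = rng.binomial(n, 0.3)
    x = rng.uniform(0.1, 0.9, size=(2, 3, 2))
    return SCMData(path_map, O, n, x, covariate_names=("prop_elderly", "prop_obese"))


@pytest.fixture
def toy_params(toy_data):
    rng = np.random.default_rng(7)
    N, K = toy_data.n_regions, toy_data.n_covariates
    p = scmap.SCMParams(
        alpha=rng.normal(size=2),
        b=rng.normal(scale=0.02, size=(2, K)),
        log_delta=rng.normal(scale=0.3),
        ush=_centered(rng, N), ssh=_centered(rng, N),
        bind=np.stack([_centered(rng, N), _centered(rng, N)]),
        bspat=np.stack([_centered(rng, N), _centered(rng, N)]),
        gamma_contrast=_centered(rng, N),
        tau_ssh=2.0, tau_ush=3.0, tau_gamma=1.5,
        tau_bspat=np.array([2.5, 4.0]), tau_bind=np.array([1.2, 0.8]),
    )
    return p


def _centered(rng, n):
    v = rng.normal(scale=0.3, size=n)
    return v - v.mean()


@pytest.fixture(scope="session")
def synthetic_subjects(zhejiang):
    """Individual-level records generated through the full synthetic pipeline."""
    truth = scmap.default_truth(zhejiang)
    data, _ = scmap.generate_regional(zhejiang, truth, 57, seed=12)
    return scmap.generate_individual(data, seed=13)
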