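import numpy as np
import pandas as pd
import pytest

from lurok.synthetic import (
    CovariateFieldSet,
    SimulationConfig,
    generate_covariates,
    generate_network,
    spatial_residual,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_years=1)


@pytest.fixture(scope="session")
def network(small_config):
    return generate_network(small_config)


@pytest.fixture(scope="session")
def site_covariates(network, small_config):
    X, meta = generate_covariates(network, small_config)
    return X, meta


def make_annual_dataset(
    seed,
    n_sites=35,
    beta=(3.0, -2.0, 2.0, -1.5),
    sill=0.0,
    range_m=15_000.0,
    noise_sd=1.0,
    intercept=40.0,
    n_variables=8,
):
    """Site-level annual means built from the package's own primitives:
    y = intercept + X·beta + spatial residual + iid noise."""
    beta_full = np.zeros(n_variables)
    beta_full[: len(beta)] = beta
    cfg = SimulationConfig(
        n_sites=n_sites,
        n_variables=n_variables,
        beta=beta_full,
        residual_sill=sill,
        residual_range=range_m,
        nugget=0.0,
        seed=seed,
    )
    net = generate_network(cfg)
    X, meta = generate_covariates(net, cfg)
    coords = net[["x", "y"]].to_numpy(float)
    rng = np.random.default_rng(seed + 10_000)
    y = (
        intercept
        + X.to_numpy() @ beta_full
        + spatial_residual(coords, sill, range_m, 0.0, rng)
        + rng.standard_normal(n_sites) * noise_sd
    )
    return net, X, meta, pd.Series(y, index=X.index), coords
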