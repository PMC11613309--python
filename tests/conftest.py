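import numpy as np
import pytest

from pinneco import synthetic


@pytest.fixture(scope="session")
def boreal_site():
    return synthetic.default_sites()[0]


@pytest.fixture(scope="session")
def climate_year(boreal_site):
    """One year of daily covariates for the boreal site (seed 0)."""
    cov = synthetic.gen_climate(boreal_site, seed=0)
    return cov.iloc[:365].reset_index(drop=True)


@pytest.fixture(scope="session")
def single_site_dataset(boreal_site):
    """Three years of observed flux data for one site."""
    dataset, _ = synthetic.make_dataset([boreal_site], seed=11)
    return dataset


@pytest.fixture(scope="session")
def multi_site_dataset():
    dataset, _ = synthetic.make_dataset(seed=7)
    return dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
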