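import numpy as np
import pytest

import pyroseasons as ps

VARS4 = ("rh", "temp", "solar", "soil")


@pytest.fixture(scope="session")
def default_run():
    """Seed-1 study-scale synthetic run (17 years, published season
    parameters) shared across tests."""
    cfg = ps.SynthConfig(seed=1)
    series, truth = ps.generate_weather(cfg)
    fm = ps.transform_and_standardize(series, VARS4)
    return cfg, series, truth, fm


@pytest.fixture(scope="session")
def small_run():
    """Fast 4-year run for pipeline plumbing tests."""
    cfg = ps.SynthConfig(seed=7, n_years=4)
    series, truth = ps.generate_weather(cfg)
    fm = ps.transform_and_standardize(series, VARS4)
    return cfg, series, truth, fm


@pytest.fixture
def rng():
    return np.random.default_rng(0)
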