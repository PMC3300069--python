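import numpy as np
import pytest

from gelfdr import SimulationConfig, bin_z, build_design, simulate_z


@pytest.fixture(scope="session")
def two_normal_config() -> SimulationConfig:
    """The standard two-normal validation model: 5000 z from N(-1,1) plus
    500 from N(3,1), null proportion 10/11, null interval [-2, 0]."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def fitted_hist_design(two_normal_config):
    """One seeded replicate binned to 100 bins with a df-7 design."""
    z, _ = simulate_z(two_normal_config, seed=7)
    hist = bin_z(z, bins=100)
    design = build_design(hist, 7, two_normal_config.null_interval)
    return hist, design


@pytest.fixture(scope="session")
def pure_null_hist_design():
    """A pure-null sample (mixture = its own null), binned, wide interval."""
    rng = np.random.default_rng(11)
    z = rng.normal(-1.0, 1.0, 5000)
    hist = bin_z(z, bins=60)
    design = build_design(hist, 5, (-2.0, 0.0))
    return hist, design
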