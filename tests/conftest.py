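import numpy as np
import pandas as pd
import pytest

from bioscatter.geometry import RadarSite, assign_gates_to_columns, build_cvp_lattice
from bioscatter.simulate import SceneConfig


@pytest.fixture(scope="session")
def site() -> RadarSite:
    return RadarSite(site_id="test-wsr", antenna_altitude=50.0)


@pytest.fixture(scope="session")
def lattice(site):
    return build_cvp_lattice(site)


@pytest.fixture(scope="session")
def mapping(site, lattice):
    return assign_gates_to_columns(lattice, site)


@pytest.fixture(scope="session")
def noiseless_config() -> SceneConfig:
    return SceneConfig(seed=7).noiseless()


@pytest.fixture(scope="session")
def noon() -> pd.Timestamp:
    # mid-season, diurnal activity peak
    return pd.Timestamp("2014-07-15 11:00")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
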