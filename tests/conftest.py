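import numpy as np
import pytest

from gppval.photosynthesis import PhotoParams
from gppval.synth import SyntheticSiteConfig, generate_site, table2_fixture


@pytest.fixture(scope="session")
def fixture62():
    return table2_fixture()


@pytest.fixture(scope="session")
def default_params():
    return PhotoParams()


@pytest.fixture(scope="session")
def noise_free_site():
    """Warm 2-year site with zero observation noise (exact closure)."""
    config = SyntheticSiteConfig(site_id="SYN-NF", pft="Tropical broadleaf trees",
                                 latitude=15.0, n_years=2, true_vcmax=65e-6,
                                 gpp_noise_sd=0.0, seed=1)
    return config, generate_site(config)


@pytest.fixture(scope="session")
def noisy_site():
    """Temperate 2-year site with 0.5 g C m-2 day-1 observation noise."""
    config = SyntheticSiteConfig(site_id="SYN-NZ", pft="Temperate broadleaf trees",
                                 latitude=40.0, n_years=2, true_vcmax=40e-6,
                                 gpp_noise_sd=0.5, seed=11)
    return config, generate_site(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
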