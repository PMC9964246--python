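import numpy as np
import pytest

from tibiofem.config import default_study_config, healthy_weight_spec, obese_spec
from tibiofem.contact import ContactGeometry, build_element_grid

SEED = 0


@pytest.fixture(scope="session")
def default_geometry():
    return ContactGeometry()


@pytest.fixture(scope="session")
def default_grid(default_geometry):
    return build_element_grid(default_geometry)


@pytest.fixture(scope="session")
def coarse_geometry():
    # 2 mm spacing keeps property-test loops fast; same footprint
    return ContactGeometry(element_spacing=2.0)


@pytest.fixture(scope="session")
def coarse_grid(coarse_geometry):
    return build_element_grid(coarse_geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def healthy_spec():
    return healthy_weight_spec()


@pytest.fixture()
def obese_spec_fixture():
    return obese_spec()


@pytest.fixture()
def study_config():
    return default_study_config(seed=SEED)
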