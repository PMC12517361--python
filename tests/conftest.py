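import numpy as np
import pytest

from uncrowding.evidence import build_templates
from uncrowding.params import GeometrySpec, ModelParams


@pytest.fixture(scope="session")
def geometry():
    return GeometrySpec()


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def no_jitter_params():
    return ModelParams(seed_jitter_arcmin=0.0)


@pytest.fixture(scope="session")
def templates(params, geometry):
    return build_templates(params, geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
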