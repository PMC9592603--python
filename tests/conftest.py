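import numpy as np
import pytest

from nanoexo import (
    GENERIC_CELL,
    WATER,
    MediumSpec,
    SurfaceChemistry,
    SyntheticSpec,
    XdlvoParameters,
    generate_np_panel,
)


@pytest.fixture(scope="session")
def cell() -> SurfaceChemistry:
    return GENERIC_CELL


@pytest.fixture(scope="session")
def water_medium() -> MediumSpec:
    return MediumSpec()


@pytest.fixture(scope="session")
def params() -> XdlvoParameters:
    return XdlvoParameters()


@pytest.fixture(scope="session")
def synthetic_panel():
    """Default synthetic NP panel: 10 coated NPs spanning 8-100 nm."""
    return generate_np_panel(SyntheticSpec(seed=0, n_nps=10))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
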