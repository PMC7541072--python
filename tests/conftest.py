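import numpy as np
import pytest

from swmrelax import (
    CellularSceneConfig,
    PhysicalConstants,
    gen_cellular_iron_map,
)


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def small_cellular_scene():
    """A reduced cellular iron scene for fast field-simulation tests."""
    config = CellularSceneConfig(
        fov_um=(96.0, 96.0), soma_density_per_um2=0.002, seed=11
    )
    return gen_cellular_iron_map(config)


@pytest.fixture(scope="session")
def default_cellular_scene():
    """The default-condition cellular scene (200 um FOV, soma fraction 0.12)."""
    return gen_cellular_iron_map(CellularSceneConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
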