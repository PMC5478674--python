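import numpy as np
import pytest

from vista import (EcologyConfig, GrowthPathways, InteractionKernel,
                   VistaConfig, WindClimatology)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def pathways():
    return GrowthPathways()


@pytest.fixture(scope="session")
def kernel():
    return InteractionKernel.from_config(EcologyConfig())


@pytest.fixture
def smoke_cfg():
    cfg = VistaConfig()
    cfg.grid.width = cfg.grid.height = 20
    return cfg


@pytest.fixture(scope="session")
def climatology():
    return WindClimatology()
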