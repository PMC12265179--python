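import numpy as np
import pytest

from fibsemga import materials as M
from fibsemga.electron_physics import HAADFCrossSectionModel


@pytest.fixture(scope="session")
def epon() -> M.Material:
    return M.preset("epon_araldite")


@pytest.fixture(scope="session")
def sigma_model() -> HAADFCrossSectionModel:
    return HAADFCrossSectionModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
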