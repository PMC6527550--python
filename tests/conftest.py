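import numpy as np
import pytest

from exopath.elasticmodes import ANMConfig, anm_modes
from exopath.synthetic import ToyPocketSpec, make_toy_pocket, toy_anm_config

TOY_ANM = toy_anm_config()


@pytest.fixture(scope="session")
def toy_pocket():
    """Default toy pocket (uncertified here; certification has its own test)."""
    return make_toy_pocket(ToyPocketSpec(), certify=False)


@pytest.fixture(scope="session")
def toy_modes(toy_pocket):
    structure, _, _ = toy_pocket
    return anm_modes(structure, TOY_ANM)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
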