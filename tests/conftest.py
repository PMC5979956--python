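import numpy as np
import pytest

from gratiomap.noddi import NoddiOptions
from gratiomap.phantom import PhantomConfig, generate_phantom, two_shell_scheme

# small geometry shared by the fast end-to-end tests
SMALL_SHAPE = (24, 24, 4)


def small_config(**overrides) -> PhantomConfig:
    defaults = dict(shape=SMALL_SHAPE, level_slices=(2,))
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def scheme():
    return two_shell_scheme()


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Noise-free, homogeneous-B1 phantom: the exact-inversion regime."""
    cfg = small_config(snr=None, b1_model="uniform")
    return generate_phantom(cfg, seed=7)


@pytest.fixture(scope="session")
def noddi_options():
    return NoddiOptions()
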