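import numpy as np
import pytest

from fretmap.io import Roi
from fretmap.simulate import AcquisitionConfig, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """Deterministic 8-patch scene with the default photon budget."""
    return make_scene(np.random.default_rng(7), n_patches=8)


@pytest.fixture
def noise_free_cfg():
    """Acquisition with quenching only: no bleach loss, no camera noise."""
    return AcquisitionConfig(E_true=0.10, beta_bleach=1.0, delta_struct=0.0,
                             read_noise_sd=0.0, rng_seed=0)


@pytest.fixture
def corner_bg_roi():
    """Extracellular strip along the top rows of a 64x64 scene."""
    return Roi("bg", "background", "polygon",
               vertices=np.array([(-0.5, -0.5), (-0.5, 63.5),
                                  (2.5, 63.5), (2.5, -0.5)]))
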