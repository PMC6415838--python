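import numpy as np
import pytest

from vesselkit import phantom


@pytest.fixture(scope="session")
def straight_tube():
    """Single straight x-aligned tube, radius 3 um, 1 um isotropic."""
    return phantom.straight_tube_phantom(shape=(32, 32, 96), radius_um=3.0)


@pytest.fixture(scope="session")
def y_junction():
    return phantom.y_junction_phantom()


@pytest.fixture(scope="session")
def small_network():
    """Three-vessel clean network in a 48x64x64 volume."""
    spec = phantom.PhantomSpec(
        volume_shape=(48, 64, 64), n_vessels=3, seed=5, noise_sigma=0.0,
        snr_decay_length_um=np.inf, motion_max_shift_px=0.0,
    )
    return phantom.generate_tube_network(spec), spec
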