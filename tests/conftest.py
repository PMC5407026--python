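import numpy as np
import pytest

from allelicburst import KineticParams, simulate_dataset
from allelicburst.simulate import MOUSE_LIKE_NOISE


@pytest.fixture
def mouse_noise():
    return MOUSE_LIKE_NOISE


@pytest.fixture
def bursty_params():
    return KineticParams(0.2, 0.2, 50.0)


@pytest.fixture
def mixed_category_dataset():
    """Small noisy dataset spanning all gene categories, fixed seed."""
    kp = KineticParams
    bursty = kp(0.2, 0.2, 60.0)
    silent = kp(0.2, 0.2, 1e-4)
    constitutive = kp(20.0, 0.05, 60.0)
    ka = [bursty] * 6 + [silent] * 2 + [constitutive] * 2 + [bursty] * 2
    kb = [bursty] * 6 + [silent] * 2 + [constitutive] * 2 + [silent] * 2
    return simulate_dataset(ka, kb, n_cells=80, sigma_size=0.1,
                            noise=MOUSE_LIKE_NOISE, seed=42)
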