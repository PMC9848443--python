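import numpy as np
import pytest

import neoscan as ns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def speckled_lesion_phantom():
    """128x192 speckled phantom with one bright heterogeneous square lesion."""
    lesion = ns.LesionSpec(((32, 32), (32, 95), (95, 95), (95, 32)),
                           mean=180.0, heterogeneity=0.3)
    spec = ns.PhantomSpec(height=128, width=192, background_mean=100.0,
                          speckle_scale=0.1, lesions=(lesion,), seed=11)
    image, masks = ns.generate_phantom(spec)
    return spec, image, masks
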