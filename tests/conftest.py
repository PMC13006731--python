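import numpy as np
import pytest

import rst2g


@pytest.fixture(scope="session")
def tiny_study():
    """An 8-slice 32x32 phantom with a centred enhancing lesion."""
    spec = rst2g.PhantomSpec(shape=(8, 32, 32), tumor_center=(4, 16, 16),
                             tumor_radii=(2.5, 8, 8), seed=3)
    return rst2g.generate_phantom(spec)


@pytest.fixture(scope="session")
def tiny_model():
    return rst2g.RST2G(rst2g.RST2GConfig.tiny((32, 32)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
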