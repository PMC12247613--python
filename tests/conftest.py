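import numpy as np
import pytest

from nexikit import TissueParameters, connectom_protocol


@pytest.fixture(scope="session")
def protocol():
    return connectom_protocol()


@pytest.fixture(scope="session")
def midpoint_d2():
    """Midpoint of the Dataset-2 (cortex-like) parameter ranges."""
    return TissueParameters(t_ex=55.5, D_i=3.0, D_e=1.0, f=0.4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


def random_params(rng, n, dataset=1):
    """Random parameter draws within the broad (Dataset-1-like) box."""
    t_ex = rng.uniform(1, 150, n)
    d_i = rng.uniform(0.1, 3.5, n)
    d_e = rng.uniform(0.1, 3.5, n)
    f = rng.uniform(0.1, 0.9, n)
    return [TissueParameters(*vals) for vals in zip(t_ex, d_i, d_e, f)]
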