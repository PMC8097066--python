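import numpy as np
import pytest

from cellhydro import build_ladder, build_matrix


@pytest.fixture(scope="session")
def ladder10():
    """The 10-cellobiose worked-example ladder (glucose-terminal)."""
    return build_ladder(10)


@pytest.fixture(scope="session")
def gauss10():
    """Conservative Gauss matrix for the 10-CB scenario, dt = 100 s."""
    return build_matrix(10, "gauss", dt=100.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210504)
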