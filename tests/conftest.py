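import numpy as np
import pytest

from brainmux.atlas import make_atlas
from brainmux.connectivity import ConnectivityMatrix
from brainmux.synthetic import CohortParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def atlas21():
    """Tiny seven-network atlas (3 regions per subnetwork)."""
    return make_atlas(21)


@pytest.fixture(scope="session")
def atlas28():
    return make_atlas(28)


def random_connectivity(n, rng, heavy=False):
    """Random symmetric positive weight matrix (complete graph)."""
    if heavy:
        w = rng.lognormal(0.0, 1.0, size=(n, n))
    else:
        w = rng.uniform(0.05, 1.0, size=(n, n))
    w = np.triu(w, 1)
    w = w + w.T
    return ConnectivityMatrix(w)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with all layers (reduced epochs, 256 Hz)."""
    params = CohortParams(
        n_subjects=6, n_regions=21, n_epochs=2, epoch_len=256,
        sampling_rate=256.0, seed=11,
    )
    return generate_cohort(params)
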