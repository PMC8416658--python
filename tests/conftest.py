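import numpy as np
import pytest

from silicomap import Ensemble, default_test_ensemble


@pytest.fixture(scope="session")
def default_ensemble():
    """The desk-scale benchmark ensemble: 210 beads, 2 domains, 70 bins."""
    return default_test_ensemble(seed=0, n_structures=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_bead_ensemble():
    """Two conformations of a 2-bead polymer: in the first the beads touch
    (distance 1 < crosslink range), in the second they are far apart, so a
    cell (0, 1) contains exactly one crosslinkable 2-bead cluster."""
    conf_close = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    conf_far = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
    return Ensemble(
        coords=np.stack([conf_close, conf_far]),
        colors=np.zeros(2, dtype=int),
        bin_of_bead=np.array([0, 1]),
    )


@pytest.fixture()
def pair_ensemble():
    return two_bead_ensemble()
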