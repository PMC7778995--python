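import numpy as np
import pytest

from ndbkit import fixtures as fx


@pytest.fixture
def tiny_ensemble():
    """3-bead chain, 2 models, deterministic coordinates."""
    from ndbkit.ndb_io import ensemble_from_arrays

    m1 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
    m2 = m1 + 0.5
    return ensemble_from_arrays(
        [m1, m2], annotations=["A1", "B1", "B3"], title="tiny"
    )


@pytest.fixture
def random_ensemble():
    return fx.make_random_ensemble(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
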