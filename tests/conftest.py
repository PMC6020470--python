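import numpy as np
import pytest

from phylotu import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_pkg():
    """Mid-size toy reference used across placement/OTU tests."""
    pkg, truth = sd.make_toy_reference(n_leaves=12, S=120, seed=42)
    return pkg, truth


@pytest.fixture(scope="session")
def tiny_pkg():
    """5-leaf reference small enough for exhaustive oracles."""
    pkg, truth = sd.make_toy_reference(n_leaves=5, S=60, seed=5)
    return pkg, truth


@pytest.fixture(scope="session")
def gtr_model():
    R = np.array([
        [0.0, 1.0, 2.5, 0.8],
        [1.0, 0.0, 0.9, 2.2],
        [2.5, 0.9, 0.0, 1.1],
        [0.8, 2.2, 1.1, 0.0],
    ])
    pi = np.array([0.3, 0.2, 0.25, 0.25])
    from phylotu.evo_models import SubstModel

    return SubstModel(name="GTR", pi=pi, R=R)
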